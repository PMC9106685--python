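"""HDF5 persistence for simulation-derived distribution sets."""

from __future__ import annotations

import h5py
import numpy as np

from .image_statistics import (
    CooccurrenceTable,
    DistributionSet,
    PosteriorTable,
    SceneGrid,
    SignalGrid,
    SimulationRanges,
)

__all__ = ["save_distributions", "load_distributions"]


def save_distributions(dists: DistributionSet, path) -> None:
    """Write tables, grids and build metadata to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["n"] = dists.n
        f.attrs["seed"] = -1 if dists.seed is None else dists.seed
        r = dists.ranges
        f.attrs["ranges"] = np.array([*r.v, *r.s, *r.m, r.interocular])
        g = f.create_group("grids")
        g.create_dataset("cd_edges", data=dists.signal_grid.cd_edges)
        g.create_dataset("cs_edges", data=dists.signal_grid.cs_edges)
        g.create_dataset("v_edges", data=dists.scene_grid.v_edges)
        g.create_dataset("m_edges", data=dists.scene_grid.m_edges)
        for cue in ("cd", "cs"):
            f.create_dataset(
                f"counts_{cue}",
                data=dists.posterior(cue).counts,
                compression="gzip",
                compression_opts=4,
            )
        f.create_dataset(
            "cooccurrence_counts",
            data=dists.cooccurrence.counts,
            compression="gzip",
            compression_opts=4,
        )


def load_distributions(path) -> DistributionSet:
    with h5py.File(path, "r") as f:
        rv = f.attrs["ranges"]
        ranges = SimulationRanges(
            v=(rv[0], rv[1]), s=(rv[2], rv[3]), m=(rv[4], rv[5]), interocular=rv[6]
        )
        signal_grid = SignalGrid(
            cd_edges=f["grids/cd_edges"][:], cs_edges=f["grids/cs_edges"][:]
        )
        scene_grid = SceneGrid(
            v_edges=f["grids/v_edges"][:], m_edges=f["grids/m_edges"][:]
        )
        seed = int(f.attrs["seed"])
        return DistributionSet(
            posterior_cd=PosteriorTable("cd", signal_grid, scene_grid, f["counts_cd"][:]),
            posterior_cs=PosteriorTable("cs", signal_grid, scene_grid, f["counts_cs"][:]),
            cooccurrence=CooccurrenceTable(signal_grid, f["cooccurrence_counts"][:]),
            n=int(f.attrs["n"]),
            seed=None if seed == -1 else seed,
            ranges=ranges,
        )
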