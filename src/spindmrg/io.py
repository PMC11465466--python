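"""MPS checkpoints in HDF5.

Layout: one group ``site_<k>`` per site tensor; inside it one dataset
per stored block, named by the flattened sector key (integers joined by
underscores, e.g. ``"0_0__1_1__1_1"`` for ((0,0),(1,1),(1,1))).  Axis
sector/dimension maps and directions are stored as group attributes;
``target``, ``mode``, ``center`` and the bond spectra sit on the file
root.  Everything needed to resume or re-measure a run is in the file.
"""

from __future__ import annotations

import json
import h5py
import numpy as np

from .block_tensor import Axis, BlockTensor
from .mps_mpo import MPS
from .symmetry import MultipletSpectrum, Sector


def _key_name(key) -> str:
    return "__".join(f"{s.n}_{s.spin2}" for s in key)


def _name_key(name: str):
    return tuple(Sector(*map(int, part.split("_"))) for part in name.split("__"))


def save_mps(state: MPS, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["n_sites"] = state.n_sites
        fh.attrs["target"] = json.dumps(list(state.target))
        fh.attrs["mode"] = state.mode
        fh.attrs["center"] = -1 if state.center is None else state.center
        fh.attrs["bond_spectra"] = json.dumps(
            [None if sp is None else sp.entries for sp in state.bond_spectra])
        for k, t in enumerate(state.tensors):
            g = fh.create_group(f"site_{k}")
            g.attrs["charge"] = json.dumps(list(t.charge))
            g.attrs["axes"] = json.dumps(
                [{"direction": ax.direction,
                  "dims": [[s.n, s.spin2, d] for s, d in ax.dims]}
                 for ax in t.axes])
            for key, blk in t.blocks.items():
                g.create_dataset(_key_name(key), data=blk)


def load_mps(path) -> MPS:
    with h5py.File(path, "r") as fh:
        n = int(fh.attrs["n_sites"])
        target = Sector(*json.loads(fh.attrs["target"]))
        mode = str(fh.attrs["mode"])
        center = int(fh.attrs["center"])
        spectra_raw = json.loads(fh.attrs["bond_spectra"])
        tensors = []
        for k in range(n):
            g = fh[f"site_{k}"]
            axes = tuple(
                Axis.make(spec["direction"],
                          {Sector(a, b): d for a, b, d in spec["dims"]})
                for spec in json.loads(g.attrs["axes"]))
            t = BlockTensor(axes, tuple(json.loads(g.attrs["charge"])))
            for name, ds in g.items():
                t.set_block(_name_key(name), np.asarray(ds))
            tensors.append(t)
    spectra = [None if e is None else MultipletSpectrum([tuple(x) for x in e])
               for e in spectra_raw]
    return MPS(tensors, target, mode, None if center < 0 else center, spectra)
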