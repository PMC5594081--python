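"""HDF5 persistence for pipeline intermediates.

One bundle file per subject accumulates datasets as stages run:
``/analytic/{band}/{phase,envelope}``, ``/idfcg/{strength,mode}``,
``/mask``, ``/nmts``, ``/strength``, ``/microstates/*``.  Every write
stamps provenance attributes (config hash, seed, package version).
"""

from __future__ import annotations

import numpy as np

from . import __version__
from .coupling import IDFCG, CouplingModeTable, WindowScheme
from .preprocess import AnalyticBank


def _stamp(group, provenance: dict | None) -> None:
    group.attrs["chronnect_version"] = __version__
    for key, val in (provenance or {}).items():
        group.attrs[key] = val


def save_bank(h5, bank: AnalyticBank, provenance: dict | None = None) -> None:
    grp = h5.require_group("analytic")
    _stamp(grp, provenance)
    grp.attrs["fs"] = bank.fs
    grp.attrs["bands"] = [b.name for b in bank.bands]
    grp.attrs["band_edges"] = [(b.f_lo, b.f_hi) for b in bank.bands]
    for band in bank.bands:
        sub = grp.require_group(band.name)
        for name, arr in (("phase", bank.phase[band.name]),
                          ("envelope", bank.envelope[band.name])):
            if name in sub:
                del sub[name]
            sub.create_dataset(name, data=arr)
        sub.attrs["transient"] = bank.transient[band.name]


def load_bank(h5) -> AnalyticBank:
    from .preprocess import BandSpec

    grp = h5["analytic"]
    bands = tuple(
        BandSpec(name, lo, hi)
        for name, (lo, hi) in zip(grp.attrs["bands"], grp.attrs["band_edges"])
    )
    bank = AnalyticBank(bands=bands, fs=float(grp.attrs["fs"]))
    for band in bands:
        sub = grp[band.name]
        bank.phase[band.name] = sub["phase"][()]
        bank.envelope[band.name] = sub["envelope"][()]
        bank.transient[band.name] = int(sub.attrs["transient"])
    return bank


def save_idfcg(h5, idfcg: IDFCG, provenance: dict | None = None) -> None:
    grp = h5.require_group("idfcg")
    _stamp(grp, provenance)
    for name, arr in (("strength", idfcg.strength), ("mode", idfcg.mode)):
        if name in grp:
            del grp[name]
        grp.create_dataset(name, data=arr)
    grp.attrs["window_width"] = idfcg.scheme.width
    grp.attrs["window_step"] = idfcg.scheme.step
    grp.attrs["window_starts"] = idfcg.scheme.starts
    for key, val in idfcg.params.items():
        grp.attrs[f"param_{key}"] = val


def load_idfcg(h5) -> IDFCG:
    grp = h5["idfcg"]
    starts = np.asarray(grp.attrs["window_starts"])
    scheme = WindowScheme(width=int(grp.attrs["window_width"]),
                          step=int(grp.attrs["window_step"]),
                          count=len(starts), starts=starts)
    params = {k[6:]: grp.attrs[k] for k in grp.attrs if k.startswith("param_")}
    return IDFCG(strength=grp["strength"][()], mode=grp["mode"][()],
                 scheme=scheme, table=CouplingModeTable(), params=params)


def save_array(h5, name: str, arr: np.ndarray, provenance: dict | None = None) -> None:
    if name in h5:
        del h5[name]
    ds = h5.create_dataset(name, data=arr)
    ds.attrs["chronnect_version"] = __version__
    for key, val in (provenance or {}).items():
        ds.attrs[key] = val


def save_microstates(h5, codebook, sts: np.ndarray,
                     provenance: dict | None = None) -> None:
    grp = h5.require_group("microstates")
    _stamp(grp, provenance)
    for name, arr in (("prototypes", codebook.prototypes),
                      ("topographies", codebook.topographies),
                      ("order", codebook.order),
                      ("occupancy", codebook.occupancy),
                      ("labels", sts)):
        if name in grp:
            del grp[name]
        grp.create_dataset(name, data=arr)
    grp.attrs["distortion"] = codebook.distortion
    if codebook.rel_error is not None:
        grp.attrs["rel_error"] = codebook.rel_error
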