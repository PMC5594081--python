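"""End-to-end per-subject and cohort orchestration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chronnectomics as chron
from . import microstates as ms
from . import ml, netmetrics, topofilter
from .coupling import CouplingModeTable, build_idfcg, make_windows
from .preprocess import DEFAULT_BANDS, Recording, preprocess_recording, read_recording

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubjectResult", "run_subject", "run_cohort"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, serializable and hashable for provenance."""

    notch_hz: float | None = 60.0
    clean: bool = False
    var_kept: float = 0.95
    artifact_win_s: float = 1.0
    width_s: float = 2.5
    step_ms: float = 20.0
    n_surr: int = 200
    alpha: float = 0.05
    bonferroni: bool = False
    filter_scheme: str = "omst"
    filter_param: float | None = None
    omst_m_max: int | None = None
    nnmf_rank: int = 8
    k: int | None = None
    k_min: int = 2
    k_max: int = 12
    k_threshold: float = 0.04
    ci_word_len: int = 7
    ci_shuffles: int = 1000
    sampen_m: int = 2
    nested_selection: bool = True
    n_perm: int = 200
    n_hidden: int = 100
    master_seed: int = 42

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def subject_seed(self, index: int) -> int:
        ss = np.random.SeedSequence([self.master_seed, index])
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SubjectResult:
    """All per-subject intermediates plus the assembled feature vector."""

    idfcg: object
    mask: np.ndarray
    nmts: np.ndarray
    strength: np.ndarray
    codebook: object
    sts: np.ndarray
    features: pd.Series
    config_hash: str
    seed: int
    chron: object = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[stage {name}] {exc}") from exc

        return wrapped

    return deco


def run_subject(
    edf_path=None,
    config: PipelineConfig | None = None,
    recording: Recording | None = None,
    out_dir=None,
    subject_index: int = 0,
    fit_microstates: bool = True,
) -> SubjectResult:
    """Run the full per-subject pipeline and optionally persist the bundle.

    Either ``edf_path`` or a pre-built ``recording`` must be given.  When
    ``fit_microstates`` is False the microstate stage is skipped (used by
    the cohort runner, which fits one shared codebook).
    """
    config = config or PipelineConfig()
    seed = config.subject_seed(subject_index)
    if recording is None:
        recording = _stage("read")(read_recording)(edf_path)

    bank = _stage("preprocess")(preprocess_recording)(
        recording, notch_hz=config.notch_hz, clean=config.clean,
        var_kept=config.var_kept, win_s=config.artifact_win_s, seed=seed)

    width = int(round(config.width_s * recording.fs))
    step = max(1, int(round(config.step_ms / 1000.0 * recording.fs)))
    margin = max(bank.transient.values())
    if recording.n_samples - 2 * margin < width:
        margin = 0
    scheme = make_windows(recording.n_samples, width, step, margin=margin)

    table = CouplingModeTable(bank.bands)
    idfcg = _stage("coupling")(build_idfcg)(
        bank, scheme, table, n_surr=config.n_surr, alpha=config.alpha,
        bonferroni=config.bonferroni, seed=seed)

    mask = _stage("topofilter")(topofilter.filter_idfcg)(
        idfcg, scheme=config.filter_scheme, param=config.filter_param,
        m_max=config.omst_m_max)

    nmts = _stage("netmetrics")(netmetrics.build_nmts)(idfcg, mask)
    strength = netmetrics.strength_series(idfcg, mask)

    codebook = sts = None
    features = None
    feats = None
    if fit_microstates:
        codebook, sts, _ = _stage("microstates")(ms.fit_microstates)(
            nmts.T, k=config.k, k_range=range(config.k_min, config.k_max + 1),
            threshold=config.k_threshold, r=config.nnmf_rank, seed=seed)
        feats = _stage("chronnectomics")(chron.compute_chronnectomics)(
            sts, idfcg.mode, strength, codebook.k, table=table,
            max_word_len=config.ci_word_len, n_shuffles=config.ci_shuffles,
            seed=seed)
        features = chron.assemble_features(feats, table)

    result = SubjectResult(
        idfcg=idfcg, mask=mask, nmts=nmts, strength=strength,
        codebook=codebook, sts=sts, features=features,
        config_hash=config.config_hash, seed=seed, chron=feats)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = Path(edf_path).stem if edf_path else f"subject{subject_index:03d}"
        _persist_subject(out_dir / f"{stem}.h5", result, config)
        if features is not None:
            features.to_frame(stem).T.to_csv(out_dir / f"{stem}_features.csv")
    return result


def _persist_subject(path, result: SubjectResult, config: PipelineConfig) -> None:
    import h5py

    from . import io as h5io

    prov = {"config_hash": result.config_hash, "seed": result.seed}
    with h5py.File(path, "w") as h5:
        h5io.save_idfcg(h5, result.idfcg, prov)
        h5io.save_array(h5, "mask", result.mask.astype(np.uint8), prov)
        h5io.save_array(h5, "nmts", result.nmts, prov)
        h5io.save_array(h5, "strength", result.strength, prov)
        if result.codebook is not None:
            h5io.save_microstates(h5, result.codebook, result.sts, prov)


def run_cohort(
    manifest: pd.DataFrame | str,
    config: PipelineConfig | None = None,
    out_dir=None,
    recordings: list[Recording] | None = None,
) -> dict:
    """Cohort-level pipeline: shared microstate codebook, features, ML.

    ``manifest`` is a DataFrame (or CSV path) with columns ``path``
    (ignored when ``recordings`` is given), ``age`` and optionally
    ``group``.  A single group-level codebook is fitted on the subjects'
    concatenated network-metric time series, each subject is encoded
    against it, and the regression (and, when both groups have >= 5
    members, classification) pipelines run on the feature table.
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    n_subj = len(manifest)
    if n_subj < 10:
        raise ValueError("cohort pipeline requires at least 10 subjects")

    partial = []
    for idx in range(n_subj):
        rec = recordings[idx] if recordings is not None else None
        path = manifest.iloc[idx].get("path") if rec is None else None
        res = run_subject(edf_path=path, config=config, recording=rec,
                          subject_index=idx, fit_microstates=False)
        partial.append(res)

    shapes = {p.nmts.shape[0] for p in partial}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent channel counts across subjects: {shapes}")

    # group-level codebook on concatenated windows
    X = np.vstack([p.nmts.T for p in partial])
    codebook, _, traj = ms.fit_microstates(
        X, k=config.k, k_range=range(config.k_min, config.k_max + 1),
        threshold=config.k_threshold, r=config.nnmf_rank,
        seed=config.master_seed)

    table = CouplingModeTable()
    rows = []
    offset = 0
    for idx, p in enumerate(partial):
        t = p.nmts.shape[1]
        sts = ms.encode(traj.V[offset : offset + t], codebook)
        offset += t
        feats = chron.compute_chronnectomics(
            sts, p.idfcg.mode, p.strength, codebook.k, table=table,
            max_word_len=min(config.ci_word_len, t),
            n_shuffles=config.ci_shuffles, seed=p.seed)
        rows.append(chron.assemble_features(feats, table))
    features = pd.DataFrame(rows).reset_index(drop=True)
    # drop non-finite (e.g. undefined SampEn) and all-constant columns:
    # they carry no cohort information and break standardization
    finite = features.replace([np.inf, -np.inf], np.nan)
    keep = finite.notna().all(axis=0) & (finite.std(axis=0) > 0)
    features_ml = features.loc[:, keep]

    ages = manifest["age"].to_numpy(dtype=float)
    reg = ml.regression_pipeline(features_ml.to_numpy(), ages,
                                 nested=config.nested_selection)
    report = {
        "n_subjects": n_subj,
        "k": int(codebook.k),
        "codebook_rel_error": codebook.rel_error,
        "config_hash": config.config_hash,
        "seed": config.master_seed,
        "regression": {"r2": reg.r2, "slope": reg.slope, "intercept": reg.intercept},
    }
    if "group" in manifest:
        groups = manifest["group"].to_numpy()
        counts = pd.Series(groups).value_counts()
        if len(counts) == 2 and counts.min() >= 5:
            cls = ml.classification_pipeline(
                features_ml.to_numpy(), groups, nested=config.nested_selection,
                n_perm=config.n_perm, n_hidden=config.n_hidden,
                seed=config.master_seed)
            report["classification"] = {
                "accuracy": cls.accuracy, "sensitivity": cls.sensitivity,
                "specificity": cls.specificity}
        else:
            logger.warning("skipping classification: need two groups with >= 5 each")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        features.to_csv(out_dir / "cohort_features.csv", index=False)
        with open(out_dir / "cohort_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
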