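"""End-to-end helpers tying the phantom generator, preprocessing, slicing
and estimators together: in-memory cohort construction, a full
motion->censor->filter->connectivity chain, and branch training with
subject-level splits."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from . import slicing as sl
from . import train_eval as te
from .estimators import FmriClassifier, SmriClassifier
from .preprocess import fmri as pf
from .volumes import load_nifti

__all__ = [
    "build_smri_arrays",
    "build_fmri_arrays",
    "full_fmri_chain",
    "load_cohort_arrays",
    "train_branch",
]


def build_smri_arrays(spec: ph.PhantomSpec, n_slices: int = 8,
                      out_size: int = 16):
    """Generate the cohort's multi-view tensors in memory.

    Returns (X, y, subject_ids) with X of shape (n, 3, n_slices, out, out).
    """
    roster = ph.make_roster(spec)
    X, y, sids = [], [], []
    for _, row in roster.iterrows():
        vol = ph.make_smri_phantom(spec, row.subject_id, row.label).volume
        stacks = {
            plane: sl.extract_plane_slices(vol, plane, n_slices,
                                           out_size=out_size,
                                           subject_id=row.subject_id)
            for plane in sl.PLANES
        }
        X.append(sl.assemble_multiview(stacks))
        y.append(row.label)
        sids.append(row.subject_id)
    return np.asarray(X), np.asarray(y), np.asarray(sids)


def build_fmri_arrays(spec: ph.PhantomSpec, bandpass: bool = True):
    """Generate the cohort's ROI time-series matrices in memory.

    Uses the generator's ground-truth motion for FD censoring (skipping
    per-frame registration keeps cohort construction fast); with no motion
    spikes every frame is retained, so X is rectangular (n, T, R).
    """
    roster = ph.make_roster(spec)
    X, y, sids = [], [], []
    for _, row in roster.iterrows():
        fmri = ph.make_fmri_phantom(spec, row.subject_id, row.label)
        fd = pf.framewise_displacement(fmri.motion)
        retained = pf.censor_frames(fd)
        ts = pf.roi_timeseries(fmri.volume, fmri.atlas, retained)
        S = pf.bandpass(ts.S, spec.tr, *spec.band) if bandpass else ts.S
        X.append(S)
        y.append(row.label)
        sids.append(row.subject_id)
    return np.asarray(X), np.asarray(y), np.asarray(sids)


def full_fmri_chain(spec: ph.PhantomSpec, subject_id: str, label: str,
                    estimate_motion: bool = True,
                    fd_threshold: float = pf.DEFAULT_FD_THRESHOLD_MM):
    """The complete functional chain for one subject: motion estimation,
    FD censoring, band-pass filtering, ROI extraction, connectivity.

    Band-pass runs on the full series; censored frames are dropped after.
    Returns (ConnectivityMatrix, retained indices, MotionTrace estimate).
    """
    fmri = ph.make_fmri_phantom(spec, subject_id, label)
    if estimate_motion:
        trace = pf.estimate_motion(fmri.volume)
    else:
        trace = fmri.motion
    fd = pf.framewise_displacement(trace)
    retained = pf.censor_frames(fd, threshold_mm=fd_threshold)
    ts_full = pf.roi_timeseries(fmri.volume, fmri.atlas)
    S_filt = pf.bandpass(ts_full.S, spec.tr, *spec.band)
    S = S_filt[retained]
    return pf.connectivity(S), retained, trace


def load_cohort_arrays(dataset_dir: Path, modality: str, n_slices: int = 8,
                       out_size: int = 16):
    """Read a phantom-gen output directory back into training arrays."""
    roster = pd.read_csv(dataset_dir / "roster.csv")
    X, y, sids = [], [], []
    if modality == "smri":
        for _, row in roster.iterrows():
            vol = load_nifti(row.smri_path)
            stacks = {
                plane: sl.extract_plane_slices(vol, plane, n_slices,
                                               out_size=out_size)
                for plane in sl.PLANES
            }
            X.append(sl.assemble_multiview(stacks))
            y.append(row.label)
            sids.append(row.subject_id)
    else:
        from .volumes import RoiAtlas
        atlas_img = load_nifti(dataset_dir / "atlas.nii.gz")
        labels = np.rint(atlas_img.data).astype(np.int32)
        atlas = RoiAtlas(labels=labels, n_rois=int(labels.max()))
        for _, row in roster.iterrows():
            vol = load_nifti(row.fmri_path)
            ts = pf.roi_timeseries(vol, atlas)
            X.append(pf.bandpass(ts.S, vol.tr))
            y.append(row.label)
            sids.append(row.subject_id)
    return np.asarray(X), np.asarray(y), np.asarray(sids)


def train_branch(data, modality: str, epochs: int = 30, seed: int = 0,
                 test_frac: float = 0.2, **est_kwargs) -> dict:
    """Subject-level split, branch training, slice- and subject-level
    evaluation; returns a JSON-ready result dict."""
    X, y, sids = data
    roster = pd.DataFrame({"subject_id": sids, "label": y})
    manifest = sl.subject_split(roster, test_frac=test_frac, seed=seed)
    is_test = (manifest["split"] == "test").to_numpy()
    if modality == "smri":
        est = SmriClassifier(epochs=epochs, seed=seed, **est_kwargs)
    else:
        est = FmriClassifier(epochs=epochs, seed=seed, **est_kwargs)
    te.fit_with_manifest(est, X, y, manifest)
    report_tr = te.evaluate(est, X[~is_test], y[~is_test],
                            subject_ids=sids[~is_test], positive_class=ph.ASD)
    if is_test.any():
        report_te = te.evaluate(est, X[is_test], y[is_test],
                                subject_ids=sids[is_test],
                                positive_class=ph.ASD)
    else:  # roster too small for a floor(0.2 n) test split
        report_te = {}
    def flat(rep):
        out = {}
        for key, val in rep.items():
            if isinstance(val, te.MetricsReport):
                out[key] = {
                    "accuracy": val.accuracy, "precision": val.precision,
                    "recall": val.recall, "specificity": val.specificity,
                    "f1": val.f1,
                }
            else:
                out[key] = val
        return out
    return {
        "modality": modality,
        "final_train_loss": float(est.history_[-1]),
        "train": flat(report_tr),
        "test": flat(report_te),
        "loss_history": [float(v) for v in est.history_],
    }
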