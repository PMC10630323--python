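"""Evaluation statistics for waveform reconstruction and vitals regression.

- ``pearson``: centered dot product over the product of centered norms.
- ``dirichlet_distance``: the worst-case pointwise distance between two
  equal-length waveforms, max_i |x_i - y_i|.  (The printed definition wraps
  this in a min over a single index set, which is vacuous and implemented as
  identity.)
- ``mae_sae``: mean absolute error and the standard deviation of the absolute
  errors (population convention, ddof=0, configurable).
- ``peak_error_table``: per-fiducial amplitude errors of reconstructed ECG
  cycles, summarized as mean (MMAE) and std (MSAE) across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .peaks import locate_pqrst

__all__ = ["pearson", "dirichlet_distance", "mae_sae", "peak_error_table"]

_FIDUCIALS = ("P", "Q", "R", "S", "T")


def pearson(x, y) -> float:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("pearson requires equal-length inputs")
    if x.size < 2:
        raise ValueError("pearson requires at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("pearson undefined for a constant input")
    return float(xc @ yc / (nx * ny))


def dirichlet_distance(x, y) -> float:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("dirichlet_distance requires equal-length inputs")
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.max(np.abs(x - y)))


def mae_sae(y_true, y_pred, ddof: int = 0) -> tuple[float, float]:
    """Mean absolute error and std of the absolute errors."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("mae_sae requires equal-length inputs")
    if y_true.size == 0:
        raise ValueError("empty input")
    err = np.abs(y_true - y_pred)
    return float(err.mean()), float(err.std(ddof=ddof))


def peak_error_table(
    pairs_by_subject: dict[object, list[tuple[np.ndarray, np.ndarray]]],
    fs: float,
    r_index: int | None = None,
) -> pd.DataFrame:
    """Amplitude errors at the five ECG fiducials, aggregated across subjects.

    ``pairs_by_subject`` maps a subject id to a list of (reference cycle,
    reconstructed cycle) pairs.  Fiducials are located on the *reference*
    cycle, and the absolute amplitude difference is taken at the reference
    fiducial's sample index on both waveforms.  Per subject the cycle errors
    are averaged; MMAE/MSAE are the mean/std of those subject means.  Cycles
    where a fiducial is absent are skipped for that fiducial, with the skip
    count reported.
    """
    if not pairs_by_subject:
        raise ValueError("need at least one subject")
    per_subject: dict[str, list[float]] = {f: [] for f in _FIDUCIALS}
    skipped = {f: 0 for f in _FIDUCIALS}
    for _, cycles in pairs_by_subject.items():
        errs: dict[str, list[float]] = {f: [] for f in _FIDUCIALS}
        for ref, rec in cycles:
            ref = np.asarray(ref, float)
            rec = np.asarray(rec, float)
            if ref.shape != rec.shape:
                raise ValueError("reference and reconstruction must share length")
            r = int(np.argmax(ref)) if r_index is None else r_index
            fids = locate_pqrst(ref, r, fs)
            present = dict(zip(fids.fiducial, fids.indices))
            for f in _FIDUCIALS:
                if f in present:
                    i = present[f]
                    errs[f].append(abs(ref[i] - rec[i]))
                else:
                    skipped[f] += 1
        for f in _FIDUCIALS:
            if errs[f]:
                per_subject[f].append(float(np.mean(errs[f])))
    rows = []
    for f in _FIDUCIALS:
        vals = np.array(per_subject[f])
        rows.append(
            {
                "fiducial": f,
                "MMAE": float(vals.mean()) if vals.size else np.nan,
                "MSAE": float(vals.std(ddof=0)) if vals.size else np.nan,
                "n_subjects": int(vals.size),
                "n_skipped": skipped[f],
            }
        )
    table = pd.DataFrame(rows).set_index("fiducial")
    if len(pairs_by_subject) == 1:
        table.attrs["single_subject"] = True  # MSAE is 0 by definition
    return table
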