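"""Growth-state assignment from heterotrophic-flagellate (HF) growth curves.

Each incubation's samples are labeled "lag", "growth", or "decline" from
their position on the HF count curve: growth starts at the first counted
time point whose HF count reaches ``onset_ratio`` times the baseline of
all preceding counts and never falls back below that level before the
peak; decline starts strictly after the peak (the peak itself belongs to
growth, and ties resolve to the later time point). The peak is located by
a rise/decline changepoint fit rather than the raw argmax, which makes
the boundary robust to counting noise on the near-flat peak plateau.
Samples taken between counted time points inherit the state of the
nearest count (ties go to the earlier point).

An ordination (PCA on variance-stabilized transcript counts) with a
silhouette score of the state grouping is provided to sanity-check the
labels; it never modifies them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import silhouette_score

from .errors import DegenerateInputError, InputError

STATES = ("lag", "growth", "decline")


def _hf_series(curve: pd.DataFrame) -> pd.DataFrame:
    required = {"time_days", "population", "cells_per_ml"}
    if not required.issubset(curve.columns):
        raise InputError(f"growth curve needs columns {sorted(required)}")
    hf = curve[curve["population"] == "hf"].sort_values("time_days")
    if hf.empty:
        raise InputError("growth curve has no HF series")
    if len(hf) < 3:
        raise InputError("HF series needs at least 3 time points to define states")
    if (hf["cells_per_ml"] < 0).any():
        raise InputError("negative cell counts")
    t = hf["time_days"].to_numpy(dtype=float)
    if not (np.diff(t) > 0).all():
        raise InputError("HF time points must be strictly increasing")
    return hf


def _peak_changepoint(t: np.ndarray, n: np.ndarray, span: int = 3) -> int:
    """Index of the last growth point (the peak) by changepoint fit.

    The HF curve is modeled as a monotone (isotonic) rise up to the peak
    followed by an exponential (log-linear) decline; among candidate
    boundaries near the counted maximum, the one minimizing the total
    squared error in log space wins, ties going to the later index so that
    decline stays strictly post-peak. On clean curves this reduces to the
    counted maximum; on noisy curves it is robust to argmax flips across
    the near-flat peak plateau.
    """
    logn = np.log(np.maximum(n, 1e-12))
    argmax = int(np.flatnonzero(n == n.max())[-1])
    iso = IsotonicRegression(increasing=True)
    best_j, best_sse = argmax, np.inf
    for j in range(max(1, argmax - span), min(len(n), argmax + span + 1)):
        fit = iso.fit_transform(t[: j + 1], logn[: j + 1])
        sse = float(((fit - logn[: j + 1]) ** 2).sum())
        if j < len(n) - 1:
            xs, ys = t[j:], logn[j:]
            coef = np.polyfit(xs, ys, 1)
            sse += float(((np.polyval(coef, xs) - ys) ** 2).sum())
        if sse <= best_sse:  # <= prefers the later boundary on ties
            best_sse, best_j = sse, j
    return best_j


def classify_states(
    curve: pd.DataFrame,
    sample_times: list[float],
    onset_ratio: float = 2.0,
) -> pd.DataFrame:
    """Assign lag/growth/decline to each sample time from the HF curve.

    Parameters
    ----------
    curve : long-form counts with columns (time_days, population, cells_per_ml);
        only the ``hf`` population rows are used. The classification is
        invariant to uniform rescaling of the counts (cells/mL vs cells/L).
    sample_times : times (days) of the metatranscriptome samples; each is
        matched to the nearest counted time point (ties -> earlier point).
    onset_ratio : growth begins at the first count >= onset_ratio x the
        minimum of all preceding counts (default 2).

    Returns a DataFrame with columns (time_days, state), one row per sample
    time, in the input order.
    """
    hf = _hf_series(curve)
    t = hf["time_days"].to_numpy(dtype=float)
    n = hf["cells_per_ml"].to_numpy(dtype=float)
    if n.max() == n.min():
        raise DegenerateInputError(
            "flat HF series (max == min): growth states are undefined")

    peak_idx = _peak_changepoint(t, n)

    # growth onset: first count reaching onset_ratio x the baseline of all
    # preceding counts and never falling back below itself before the peak.
    # The baseline is the geometric mean of the preceding counts — equal to
    # their minimum on a clean flat lag, but unbiased under multiplicative
    # count noise (the running minimum drifts low).
    onset_idx = None
    for i in range(1, peak_idx + 1):
        baseline = float(np.exp(np.mean(np.log(np.maximum(n[:i], 1e-12)))))
        if n[i] >= onset_ratio * baseline and n[i:peak_idx + 1].min() >= n[i]:
            onset_idx = i
            break
    if onset_idx is None:
        onset_idx = peak_idx  # growth never detected before the peak itself

    point_state = np.empty(len(t), dtype=object)
    point_state[:onset_idx] = "lag"
    point_state[onset_idx:peak_idx + 1] = "growth"
    point_state[peak_idx + 1:] = "decline"

    rows = []
    for st in sample_times:
        dist = np.abs(t - float(st))
        nearest = int(np.flatnonzero(dist == dist.min())[0])  # tie -> earlier
        rows.append((float(st), point_state[nearest]))
    return pd.DataFrame(rows, columns=["time_days", "state"])


def classify_all_incubations(
    curves: pd.DataFrame,
    samples: pd.DataFrame,
    onset_ratio: float = 2.0,
) -> pd.DataFrame:
    """Classify every incubation's samples; returns (sample_id, incubation,
    time_days, state) in the input sample order."""
    required = {"sample_id", "incubation", "time_days"}
    if not required.issubset(samples.columns):
        raise InputError(f"samples table needs columns {sorted(required)}")
    out = []
    for inc, grp in samples.groupby("incubation", sort=False):
        curve = curves[curves["incubation"] == inc]
        labeled = classify_states(curve, list(grp["time_days"]), onset_ratio)
        out.append(pd.DataFrame({
            "sample_id": grp["sample_id"].to_numpy(),
            "incubation": inc,
            "time_days": labeled["time_days"].to_numpy(),
            "state": labeled["state"].to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def variance_stabilize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count / library size * 1e6 + 1): a monotone variance-stabilizing
    transform for library-size-confounded counts (samples in columns)."""
    if (counts < 0).to_numpy().any():
        raise InputError("counts must be non-negative")
    lib = counts.sum(axis=0)
    lib = lib.replace(0, 1.0)
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def validate_states_pca(
    transcript_counts: pd.DataFrame,
    states: pd.DataFrame,
    n_components: int = 2,
) -> pd.DataFrame:
    """Ordination check of the state labels.

    PCA on variance-stabilized counts (samples in the columns of
    ``transcript_counts``, matching ``states['sample_id']``), followed by a
    mean silhouette score of the state grouping on the two components.

    Returns a DataFrame (sample_id, pc1, pc2, state, silhouette); the
    silhouette column is NaN (with a warning) when fewer than two states are
    present or there are too few samples.
    """
    sample_ids = list(states["sample_id"])
    missing = [s for s in sample_ids if s not in transcript_counts.columns]
    if missing:
        raise InputError(f"count table lacks samples: {missing}")
    mat = variance_stabilize(transcript_counts[sample_ids])
    if len(sample_ids) < 3:
        warnings.warn("fewer than 3 samples: ordination skipped")
        return pd.DataFrame({"sample_id": sample_ids, "pc1": np.nan, "pc2": np.nan,
                             "state": states["state"].to_numpy(), "silhouette": np.nan})
    x = mat.to_numpy(dtype=float).T
    pca = PCA(n_components=min(n_components, len(sample_ids) - 1, x.shape[1]),
              svd_solver="full")  # deterministic
    coords = pca.fit_transform(x)
    labels = states["state"].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2 or len(sample_ids) <= len(uniq):
        warnings.warn("silhouette undefined: need >=2 states and more samples than states")
        sil = np.nan
    else:
        sil = float(silhouette_score(coords[:, :2], labels))
    return pd.DataFrame({
        "sample_id": sample_ids,
        "pc1": coords[:, 0],
        "pc2": coords[:, 1] if coords.shape[1] > 1 else np.nan,
        "state": labels,
        "silhouette": sil,
    })
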