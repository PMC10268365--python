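"""Lag-to-growth fold change against the housekeeping baseline.

Per incubation, each gene's fold change is (mean growth TPM + eps) /
(mean lag TPM + eps); the baseline is the average fold change of the
housekeeping genes in that incubation, and a gene exceeds the baseline
when its own fold change is larger. Genes exceeding the baseline in at
least ``min_incubations`` incubations are flagged as putative
bacterivory-induced genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError


def compute_fold_changes(
    ko_table: pd.DataFrame,
    states: pd.DataFrame,
    hk: set[str],
    epsilon: float = 0.01,
    baseline: str = "arithmetic",
) -> pd.DataFrame:
    """Per-gene, per-incubation fold change and housekeeping baseline.

    Parameters
    ----------
    ko_table : gene x sample TPM table.
    states : (sample_id, incubation, state) labels.
    hk : housekeeping gene ids present in ``ko_table``.
    epsilon : pseudocount added to both state means so the ratio is finite
        when lag expression is zero.
    baseline : "arithmetic" (mean of per-gene ratios) or "geometric".

    Returns a DataFrame with columns (gene_id, incubation, fc, hk_baseline,
    exceeds_baseline). Incubations lacking a lag or growth sample are skipped
    with a warning.
    """
    hk_present = [g for g in sorted(hk) if g in ko_table.index]
    if not hk_present:
        raise DegenerateInputError("no housekeeping gene in the table: baseline undefined")
    if baseline not in ("arithmetic", "geometric"):
        raise InputError(f"unknown baseline mean: {baseline!r}")

    frames = []
    for inc, grp in states.groupby("incubation", sort=False):
        lag_cols = [s for s in grp.loc[grp["state"] == "lag", "sample_id"]
                    if s in ko_table.columns]
        growth_cols = [s for s in grp.loc[grp["state"] == "growth", "sample_id"]
                       if s in ko_table.columns]
        if not lag_cols or not growth_cols:
            warnings.warn(f"incubation {inc} lacks a lag or growth sample; skipped")
            continue
        fc = (ko_table[growth_cols].mean(axis=1) + epsilon) / \
             (ko_table[lag_cols].mean(axis=1) + epsilon)
        hk_fc = fc.loc[hk_present]
        if baseline == "arithmetic":
            base = float(hk_fc.mean())
        else:
            base = float(np.exp(np.log(hk_fc).mean()))
        frames.append(pd.DataFrame({
            "gene_id": fc.index,
            "incubation": inc,
            "fc": fc.to_numpy(),
            "hk_baseline": base,
            "exceeds_baseline": (fc > base).to_numpy(),
        }))
    if not frames:
        raise InputError("no incubation had both lag and growth samples")
    return pd.concat(frames, ignore_index=True)


def flag_candidates(records: pd.DataFrame, min_incubations: int = 3) -> set[str]:
    """Genes exceeding the housekeeping baseline in >= ``min_incubations``
    incubations. A gene absent from an incubation's records simply counts as
    not exceeding there (conservative)."""
    required = {"gene_id", "exceeds_baseline"}
    if not required.issubset(records.columns):
        raise InputError(f"records need columns {sorted(required)}")
    wins = records.groupby("gene_id")["exceeds_baseline"].sum()
    return set(wins.index[wins >= min_incubations])
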