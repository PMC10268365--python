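"""Per-species expression normalization.

Raw CDS read counts are divided by effective length, rescaled to an
integer 0..10^6 composition with a pseudocount, corrected for
between-sample composition bias with TMM (trimmed mean of M-values)
factors, and expressed as pseudocounts per million. By default each
species' CDS matrix is normalized on its own.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError


def length_correct(raw_counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Divide each CDS row by its effective length (elementwise)."""
    lengths = effective_lengths.reindex(raw_counts.index)
    bad = lengths.isna() | (lengths <= 0)
    if bad.any():
        raise InputError(
            f"non-positive or missing effective length for CDS: {list(lengths.index[bad][:5])}")
    return raw_counts.div(lengths, axis=0)


def integerize(
    lc_counts: pd.DataFrame,
    scale: int = 10**6,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Convert length-corrected abundances to an integer 0..scale composition.

    Per sample: scale the column to sum to ``scale``, add ``pseudocount`` to
    every CDS, round half away from zero, cap at ``scale``.
    """
    arr = lc_counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise InputError("negative length-corrected counts")
    sums = arr.sum(axis=0)
    if (sums <= 0).any():
        zero_cols = [c for c, s in zip(lc_counts.columns, sums) if s <= 0]
        raise DegenerateInputError(f"all-zero sample(s): {zero_cols}; composition undefined")
    scaled = arr / sums * scale + pseudocount
    ints = np.floor(scaled + 0.5)  # round half away from zero (values are >= 0)
    ints = np.minimum(ints, scale).astype(np.int64)
    return pd.DataFrame(ints, index=lc_counts.index, columns=lc_counts.columns)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """TMM normalization factors (trimmed mean of M-values).

    The reference sample is the one whose 75th percentile of library-scaled
    counts is closest to the mean of those percentiles. For each sample,
    genes with a zero count in either the sample or the reference are
    removed; M = log2 of the ratio of library-scaled abundances and
    A = their average log2 abundance are doubly trimmed (``trim_m`` of the M
    distribution and ``trim_a`` of the A distribution, each from both tails);
    the factor is 2 to the inverse-asymptotic-variance-weighted mean of the
    trimmed M values. Factors are rescaled so their geometric mean is 1.

    A sample sharing no positive gene with the reference gets factor 1 with
    a warning, as does a sample whose M values are all (numerically) zero.
    """
    if counts.shape[1] < 2:
        raise InputError("TMM needs at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise InputError("every sample needs at least one positive count")

    f75 = np.quantile(arr / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    for s in range(counts.shape[1]):
        if s == ref:
            factors[s] = _tmm_pair(arr[:, s], arr[:, s], lib[s], lib[s],
                                   trim_m, trim_a, weighted)
            continue
        factors[s] = _tmm_pair(arr[:, s], arr[:, ref], lib[s], lib[ref],
                               trim_m, trim_a, weighted)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a, weighted) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("sample shares no positive gene with the reference; factor 1")
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()  # average ranks on ties
    rank_a = pd.Series(a).rank().to_numpy()
    kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not kept.any():
        return 1.0
    if weighted:
        w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
        f = np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])
    else:
        f = np.mean(m[kept])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def to_cpm(
    counts: pd.DataFrame,
    factors: pd.Series,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Pseudocounts per million: (count + prior) / (library size x factor) x 10^6.

    With ``prior`` 0 every column sums exactly to 10^6 / factor-weighted
    library — i.e. plain per-million normalization on the effective library.
    """
    lib = counts.sum(axis=0).astype(float)
    eff = lib * factors.reindex(counts.columns)
    return (counts + prior).div(eff, axis=1) * 1e6


def species_totals(cpm: pd.DataFrame, species_map: pd.Series) -> pd.DataFrame:
    """Sum CPM over each species' CDS per sample (species x sample table)."""
    sp = species_map.reindex(cpm.index)
    if sp.isna().any():
        raise InputError(f"CDS without species mapping: {list(sp.index[sp.isna()][:5])}")
    return cpm.groupby(sp).sum()


def quantify_species(
    counts_long: pd.DataFrame,
    pseudocount: float = 1.0,
    prior: float = 0.5,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    pooled: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full normalization of a long-form count table.

    ``counts_long`` has columns (species, cds_id, sample, read_count,
    effective_length). Each species is normalized separately (length
    correction, integerization, TMM, CPM) unless ``pooled`` is set, in which
    case one TMM pass runs over the stacked CDS matrix of all species.

    Returns (cpm_long, totals) where cpm_long has columns (species, cds_id,
    sample, cpm) and totals is a species x sample table of summed CPM.
    """
    required = {"species", "cds_id", "sample", "read_count", "effective_length"}
    if not required.issubset(counts_long.columns):
        raise InputError(f"count table needs columns {sorted(required)}")

    def _normalize(group: pd.DataFrame) -> pd.DataFrame:
        wide = group.pivot_table(index="cds_id", columns="sample",
                                 values="read_count", aggfunc="sum", fill_value=0)
        lengths = group.drop_duplicates("cds_id").set_index("cds_id")["effective_length"]
        lc = length_correct(wide, lengths)
        ints = integerize(lc, pseudocount=pseudocount)
        factors = tmm_factors(ints, trim_m=trim_m, trim_a=trim_a)
        return to_cpm(ints, factors, prior=prior)

    if pooled:
        key = counts_long["species"].astype(str) + "::" + counts_long["cds_id"].astype(str)
        tagged = counts_long.assign(cds_id=key)
        cpm = _normalize(tagged)
        ids = cpm.index.to_series().str.split("::", expand=True)
        cpm_long = cpm.reset_index(drop=True)
        cpm_long.insert(0, "cds_id", ids[1].to_numpy())
        cpm_long.insert(0, "species", ids[0].to_numpy())
        cpm_long = cpm_long.melt(id_vars=["species", "cds_id"],
                                 var_name="sample", value_name="cpm")
    else:
        parts = []
        for sp, group in counts_long.groupby("species", sort=True):
            cpm = _normalize(group)
            part = cpm.reset_index().melt(id_vars="cds_id",
                                          var_name="sample", value_name="cpm")
            part.insert(0, "species", sp)
            parts.append(part)
        cpm_long = pd.concat(parts, ignore_index=True)

    totals = cpm_long.pivot_table(index="species", columns="sample",
                                  values="cpm", aggfunc="sum", fill_value=0.0)
    return cpm_long, totals
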