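"""Community-level KO expression: filtering, pooling, overlap grouping,
category scaling, and gene-set selection.

The transcript table is a DataFrame with columns ``transcript_id``,
``ko_ids`` (semicolon-joined, possibly empty), ``taxon``, plus one TPM
column per sample. KO tables are DataFrames indexed by KO (or KO-group)
id with one column per sample.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError

META_COLUMNS = ("transcript_id", "ko_ids", "taxon")


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _ko_lists(table: pd.DataFrame) -> list[list[str]]:
    return [str(k).split(";") if isinstance(k, str) and k else []
            for k in table["ko_ids"]]


def filter_expressed(table: pd.DataFrame, min_tpm: float = 2.0) -> pd.DataFrame:
    """Keep transcripts with >= ``min_tpm`` TPM in at least one sample.

    The threshold is inclusive. Columns are NOT renormalized afterwards:
    retained TPM values keep their original scale (use
    :func:`renormalize_tpm` for an explicit rescale to 10^6).
    """
    if table.empty:
        raise InputError("empty transcript table")
    cols = sample_columns(table)
    tpm = table[cols].to_numpy(dtype=float)
    if (tpm < 0).any():
        raise InputError("negative TPM values")
    keep = (tpm >= min_tpm).any(axis=1)
    return table.loc[keep].reset_index(drop=True)


def renormalize_tpm(table: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample column of a (filtered) table to sum to 10^6."""
    out = table.copy()
    cols = sample_columns(table)
    sums = out[cols].sum(axis=0)
    out[cols] = out[cols].div(sums.replace(0, 1.0), axis=1) * 1e6
    return out


def pool_kos(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, frozenset]]:
    """Pool transcript TPM into a KO x sample table.

    A transcript annotated with k KOs contributes its full TPM to each of
    them (the duplication that :func:`group_overlapping_kos` later removes);
    unannotated transcripts are excluded.

    Returns (ko_table, ko_transcripts) where ko_transcripts maps each KO to
    the frozenset of transcript ids behind it.
    """
    cols = sample_columns(table)
    ko_lists = _ko_lists(table)
    rows: dict[str, np.ndarray] = {}
    members: dict[str, set[str]] = {}
    tpm = table[cols].to_numpy(dtype=float)
    tids = table["transcript_id"].to_numpy()
    for i, kos in enumerate(ko_lists):
        for ko in kos:
            if ko in rows:
                rows[ko] = rows[ko] + tpm[i]
                members[ko].add(tids[i])
            else:
                rows[ko] = tpm[i].copy()
                members[ko] = {tids[i]}
    ko_table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    ko_table = ko_table.sort_index()
    ko_table.index.name = "gene_id"
    return ko_table, {k: frozenset(v) for k, v in members.items()}


def compute_ko_overlap(
    ko_transcripts: dict[str, frozenset],
    kos: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pairwise annotation overlap, in percent.

    overlap(A, B) = 100 * |transcripts with both A and B| / |transcripts of A|
    — asymmetric: the denominator is the row KO's transcript count. KOs with
    no transcripts are excluded with a warning.
    """
    if kos is None:
        kos = ko_transcripts.keys()
    kos = sorted(kos)
    empty = [k for k in kos if not ko_transcripts.get(k)]
    if empty:
        warnings.warn(f"KOs without transcripts excluded from overlap: {empty}")
        kos = [k for k in kos if k not in set(empty)]
    mat = pd.DataFrame(0.0, index=kos, columns=kos)
    for a in kos:
        ta = ko_transcripts[a]
        for b in kos:
            mat.loc[a, b] = 100.0 * len(ta & ko_transcripts[b]) / len(ta)
    return mat


def group_overlapping_kos(overlap: pd.DataFrame, threshold: float = 50.0) -> list[set[str]]:
    """Single-linkage components of the overlap graph.

    Two KOs are connected when max(overlap(A,B), overlap(B,A)) >= threshold;
    each connected component is one group. Returns groups sorted by their
    smallest member.
    """
    kos = list(overlap.index)
    parent = {k: k for k in kos}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    vals = overlap.to_numpy(dtype=float)
    for i, a in enumerate(kos):
        for j in range(i + 1, len(kos)):
            if max(vals[i, j], vals[j, i]) >= threshold:
                ra, rb = find(a), find(kos[j])
                if ra != rb:
                    parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for k in kos:
        groups.setdefault(find(k), set()).add(k)
    return sorted(groups.values(), key=lambda g: min(g))


def group_id(group: set[str]) -> str:
    return "+".join(sorted(group))


def pool_groups(
    table: pd.DataFrame,
    groups: list[set[str]],
    ko_transcripts: dict[str, frozenset],
) -> pd.DataFrame:
    """Pool TPM over each group's *union* of member transcripts (each
    transcript counted once, removing the multi-KO duplication)."""
    cols = sample_columns(table)
    tpm = table[cols].to_numpy(dtype=float)
    idx_of = {t: i for i, t in enumerate(table["transcript_id"])}
    rows = {}
    for g in groups:
        union: set[str] = set()
        for ko in g:
            union |= set(ko_transcripts.get(ko, frozenset()))
        sel = [idx_of[t] for t in union if t in idx_of]
        rows[group_id(g)] = tpm[sel].sum(axis=0) if sel else np.zeros(len(cols))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()
    out.index.name = "gene_id"
    return out


def scale_categories(
    ko_table: pd.DataFrame,
    category_map: pd.Series,
    sample_incubation: pd.Series,
) -> pd.DataFrame:
    """Scale TPM to 0-100 within each (category, incubation).

    Every value is divided by the maximum TPM of its category within its
    incubation and multiplied by 100, so each (category, incubation) block
    has maximum exactly 100 (all-zero blocks stay zero, with a warning).
    KOs missing from ``category_map`` are dropped.
    """
    kos = [k for k in ko_table.index if k in category_map.index]
    scaled = ko_table.loc[kos].astype(float).copy()
    cats = category_map.loc[kos]
    for inc in sample_incubation.unique():
        cols = [s for s in ko_table.columns if sample_incubation.get(s) == inc]
        if not cols:
            continue
        for cat in cats.unique():
            rows = cats.index[cats == cat]
            block = scaled.loc[rows, cols]
            m = block.to_numpy().max() if block.size else 0.0
            if m <= 0:
                warnings.warn(f"category {cat!r} all zero in {inc}; left as zeros")
                continue
            scaled.loc[rows, cols] = block / m * 100.0
    return scaled


def select_highly_expressed(
    ko_table: pd.DataFrame,
    states: pd.DataFrame,
    min_mean_tpm: float = 500.0,
    growth_only: bool = True,
) -> set[str]:
    """KOs whose mean TPM exceeds ``min_mean_tpm`` (strictly) in at least one
    incubation; by default the mean is taken over that incubation's
    growth-state samples only. Incubations without growth samples are skipped.
    """
    selected: set[str] = set()
    for inc, grp in states.groupby("incubation", sort=False):
        sub = grp[grp["state"] == "growth"] if growth_only else grp
        cols = [s for s in sub["sample_id"] if s in ko_table.columns]
        if not cols:
            continue
        means = ko_table[cols].mean(axis=1)
        selected |= set(means.index[means > min_mean_tpm])
    return selected


def load_housekeeping(
    source: str | Path | Iterable[str],
    ko_table: pd.DataFrame,
) -> tuple[set[str], list[str]]:
    """Intersect a housekeeping KO list with the KO table.

    ``source`` is a path to a one-KO-per-line file or an iterable of ids.
    Returns (present, missing); missing ids only warn, but an empty
    intersection is an error because the fold-change baseline would be
    undefined.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
        wanted = [ln.strip() for ln in lines if ln.strip()]
    else:
        wanted = [str(k) for k in source]
    if not wanted:
        raise InputError("housekeeping list is empty")
    present = {k for k in wanted if k in ko_table.index}
    missing = sorted(set(wanted) - present)
    if missing:
        warnings.warn(f"{len(missing)} housekeeping KOs absent from the KO table")
    if not present:
        raise DegenerateInputError(
            "no housekeeping KO found in the KO table: baseline undefined")
    return present, missing
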