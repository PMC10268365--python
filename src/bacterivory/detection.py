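"""Reference-species detection from tabular alignments.

Transcripts are assigned to reference species from protein-level
alignments (identity/length filters first, then best bitscore; equal-score
top hits to two species discard the transcript), species with enough
assigned transcripts in some incubation become candidates, and candidates
are accepted only when the median nucleotide identity of their transcripts
against the species' own coding sequences exceeds a strict threshold —
otherwise the signal is attributed to a close relative of the reference.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                   "qstart", "qend", "sstart", "send", "evalue", "bitscore"]

STATUS_ACCEPTED = "accepted"
STATUS_CANDIDATE = "candidate"
STATUS_REJECTED_RELATIVE = "rejected_relative"
STATUS_REJECTED_LOW_SUPPORT = "rejected_low_support"


def read_outfmt6(path: str | Path) -> pd.DataFrame:
    """Read a headerless BLAST/DIAMOND outfmt-6 table (12 standard columns,
    1-based inclusive coordinates). Malformed rows are logged and skipped."""
    try:
        df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, header=None,
                         comment="#", on_bad_lines="warn")
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read alignment table {path}: {exc}") from exc
    numeric = ["pident", "length", "mismatch", "gapopen", "qstart", "qend",
               "sstart", "send", "evalue", "bitscore"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[numeric].isna().any(axis=1)
    if bad.any():
        logger.error("skipping %d malformed alignment rows in %s", int(bad.sum()), path)
        df = df[~bad]
    return df.reset_index(drop=True)


def attach_species(hits: pd.DataFrame, species_map: pd.DataFrame) -> pd.DataFrame:
    """Add a ``species_id`` column by mapping ``sseqid`` through a
    (subject_id, species_id) table; unmapped subjects are an error."""
    mapping = dict(zip(species_map["subject_id"], species_map["species_id"]))
    species = hits["sseqid"].map(mapping)
    if species.isna().any():
        unmapped = sorted(hits.loc[species.isna(), "sseqid"].unique()[:5])
        raise InputError(f"subjects missing from the species map, e.g. {unmapped}")
    out = hits.copy()
    out["species_id"] = species
    return out


def assign_top_hits(
    hits: pd.DataFrame,
    min_pident: float = 90.0,
    min_aln: int = 50,
    bitscore_decimals: int = 2,
) -> pd.DataFrame:
    """Assign each transcript to one species by its top-scoring protein hit.

    The identity (> ``min_pident``, strict) and alignment-length
    (>= ``min_aln``, inclusive) filters are applied BEFORE top-hit selection
    — the order matters and is fixed. Per transcript the highest bitscore
    wins; when the top score (bitscore rounded to ``bitscore_decimals``, or
    equal e-value) is shared by hits to two or more distinct species the
    transcript is discarded entirely. Ties within one species are harmless.

    Returns a DataFrame (qseqid, species_id) with one row per assigned
    transcript, sorted by qseqid.
    """
    if "species_id" not in hits.columns:
        raise InputError("hits need a species_id column (see attach_species)")
    kept = hits[(hits["pident"] > min_pident) & (hits["length"] >= min_aln)]
    if kept.empty:
        return pd.DataFrame(columns=["qseqid", "species_id"])
    kept = kept.sort_values(["qseqid", "bitscore", "sseqid"],
                            ascending=[True, False, True], kind="mergesort")
    rounding = 10.0 ** (-bitscore_decimals)
    rows = []
    for qid, grp in kept.groupby("qseqid", sort=True):
        raw = grp["bitscore"].to_numpy(dtype=float)
        bits = np.round(raw, bitscore_decimals)
        ev = grp["evalue"].to_numpy(dtype=float)
        # tied at the top: equal rounded bitscore, or equal e-value when the
        # bitscores differ only within rounding precision
        at_top = (bits == bits[0]) | ((ev == ev[0]) & (np.abs(raw - raw[0]) <= rounding))
        species = grp.loc[at_top, "species_id"].unique()
        if len(species) > 1:
            continue  # ambiguous top hit: transcript removed
        rows.append((qid, species[0]))
    return pd.DataFrame(rows, columns=["qseqid", "species_id"])


def _incubation_of(qseqid: str) -> str:
    return str(qseqid).split("_", 1)[0]


def nominate_candidates(
    assignments: pd.DataFrame,
    min_transcripts: int = 100,
    incubation_of=None,
) -> pd.DataFrame:
    """Species whose assigned-transcript count reaches ``min_transcripts``
    (inclusive) in at least one incubation become candidates; the rest are
    rejected for low support.

    ``assignments`` is (qseqid, species_id); the incubation of a transcript
    is derived from its id prefix unless ``incubation_of`` (a callable or a
    qseqid -> incubation mapping) says otherwise.

    Returns (species_id, n_transcripts_max, status).
    """
    if incubation_of is None:
        inc = assignments["qseqid"].map(_incubation_of)
    elif callable(incubation_of):
        inc = assignments["qseqid"].map(incubation_of)
    else:
        inc = assignments["qseqid"].map(dict(incubation_of))
    counts = (assignments.assign(incubation=inc)
              .groupby(["species_id", "incubation"]).size())
    max_counts = counts.groupby("species_id").max()
    return pd.DataFrame({
        "species_id": max_counts.index,
        "n_transcripts_max": max_counts.to_numpy(dtype=int),
        "status": np.where(max_counts.to_numpy() >= min_transcripts,
                           STATUS_CANDIDATE, STATUS_REJECTED_LOW_SUPPORT),
    }).reset_index(drop=True)


def verify_nucleotide_identity(
    candidates: pd.DataFrame,
    assignments: pd.DataFrame,
    nt_hits: pd.DataFrame,
    min_median: float = 99.0,
) -> pd.DataFrame:
    """Accept or reject each candidate by median nucleotide identity.

    For every candidate species, the nucleotide hits are restricted to its
    assigned transcripts against its own CDS; per transcript only the best
    (highest-bitscore) hit votes, and the species is accepted iff the median
    of those identities is strictly above ``min_median`` — otherwise it is
    labeled ``rejected_relative`` (a close relative of the reference, the
    90-95% identity band). Candidates with no nucleotide hits are rejected
    with a warning.

    Returns the candidates table with ``median_nt_identity`` and final
    ``status`` columns.
    """
    if "species_id" not in nt_hits.columns:
        raise InputError("nucleotide hits need a species_id column (see attach_species)")
    out = candidates.copy()
    out["median_nt_identity"] = np.nan
    assigned = {sp: set(grp["qseqid"])
                for sp, grp in assignments.groupby("species_id")}
    for i, row in out.iterrows():
        if row["status"] != STATUS_CANDIDATE:
            continue
        sp = row["species_id"]
        sub = nt_hits[(nt_hits["species_id"] == sp)
                      & (nt_hits["qseqid"].isin(assigned.get(sp, set())))]
        if sub.empty:
            warnings.warn(f"candidate {sp} has no nucleotide hits; rejected as relative")
            out.loc[i, "status"] = STATUS_REJECTED_RELATIVE
            continue
        best = (sub.sort_values(["qseqid", "bitscore"], ascending=[True, False],
                                kind="mergesort")
                .groupby("qseqid", sort=False).first())
        med = float(np.median(best["pident"].to_numpy(dtype=float)))
        out.loc[i, "median_nt_identity"] = med
        out.loc[i, "status"] = STATUS_ACCEPTED if med > min_median else STATUS_REJECTED_RELATIVE
    return out


def detect_species(
    protein_hits: pd.DataFrame,
    nt_hits: pd.DataFrame,
    species_map: pd.DataFrame,
    min_pident: float = 90.0,
    min_aln: int = 50,
    min_transcripts: int = 100,
    min_median: float = 99.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full detection pass: top-hit assignment, candidacy, nucleotide
    verification. Returns (candidates, assignments)."""
    prot = attach_species(protein_hits, species_map)
    nt = attach_species(nt_hits, species_map)
    assignments = assign_top_hits(prot, min_pident=min_pident, min_aln=min_aln)
    if assignments.empty:
        return (pd.DataFrame(columns=["species_id", "n_transcripts_max",
                                      "median_nt_identity", "status"]),
                assignments)
    candidates = nominate_candidates(assignments, min_transcripts=min_transcripts)
    verified = verify_nucleotide_identity(candidates, assignments, nt,
                                          min_median=min_median)
    return verified, assignments
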