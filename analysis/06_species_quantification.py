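"""Normalize per-species CDS read counts to pseudocounts per million
(effective-length correction, integer composition, TMM, CPM) and summarize
each species' expression trajectory by trophic mode.

Writes species_cpm.tsv and species_totals.tsv to results/.
"""

from pathlib import Path

import pandas as pd

from bacterivory import quant as Q

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = pd.read_csv(ROOT / "data" / "species_counts.tsv", sep="\t")
    meta = pd.read_csv(ROOT / "data" / "species_metadata.tsv", sep="\t")
    states = pd.read_csv(ROOT / "sample_states.tsv", sep="\t")

    cpm_long, totals = Q.quantify_species(counts)
    cpm_long.to_csv(ROOT / "species_cpm.tsv", sep="\t", index=False)
    totals.to_csv(ROOT / "species_totals.tsv", sep="\t")

    # library-size trend by trophic mode (the sequencing-depth signal that
    # CPM normalization removes within species)
    depth = (counts.assign(expr=counts["read_count"] / counts["effective_length"])
             .groupby(["species", "sample"])["expr"].sum().reset_index())
    depth["state"] = depth["sample"].map(
        dict(zip(states["sample_id"], states["state"])))
    depth["mode"] = depth["species"].map(
        dict(zip(meta["species"], meta["trophic_mode"])))
    trend = depth.groupby(["mode", "state"])["expr"].mean().unstack()
    trend = trend[[c for c in ("lag", "growth", "decline") if c in trend]]
    print(f"normalized {totals.shape[0]} species x {totals.shape[1]} samples")
    print("mean length-corrected depth by trophic mode and state:")
    print(trend.round(1).to_string())


if __name__ == "__main__":
    main()
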