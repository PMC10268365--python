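"""Detect which reference species are present in the incubations from the
protein alignments, then verify each candidate at the nucleotide level.

Writes species_candidates.tsv to results/ and compares the accepted set with
the planted truth.
"""

import json
from pathlib import Path

import pandas as pd

from bacterivory import detection as D

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    prot = D.read_outfmt6(ROOT / "data" / "protein_hits.tsv")
    nt = D.read_outfmt6(ROOT / "data" / "nucleotide_hits.tsv")
    smap = pd.read_csv(ROOT / "data" / "species_map.tsv", sep="\t")

    candidates, assignments = D.detect_species(prot, nt, smap)
    candidates.to_csv(ROOT / "species_candidates.tsv", sep="\t", index=False)

    truth = json.loads((ROOT / "data" / "truth.json").read_text())["species_status"]
    accepted = set(candidates.loc[candidates["status"] == "accepted", "species_id"])
    present = {s for s, st in truth.items() if st == "present"}
    print(f"{assignments['qseqid'].nunique()} transcripts assigned to "
          f"{candidates.shape[0]} species with any support")
    print(candidates["status"].value_counts().to_string())
    print(f"accepted == planted present: {accepted == present}")


if __name__ == "__main__":
    main()
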