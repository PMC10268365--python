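"""Score every KO group by its lag-to-growth fold change against the
housekeeping baseline and flag genes exceeding it in >= 3 of 4 incubations.

Writes fold_changes.tsv and fc_flagged.tsv to results/ and reports how many
planted markers were flagged.
"""

import json
from pathlib import Path

import pandas as pd

from bacterivory import community as C, foldchange as F

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    grouped = pd.read_csv(ROOT / "ko_groups_table.tsv", sep="\t", index_col=0)
    states = pd.read_csv(ROOT / "sample_states.tsv", sep="\t")
    hk, missing = C.load_housekeeping(ROOT / "data" / "housekeeping_kos.txt", grouped)

    fcs = F.compute_fold_changes(grouped, states, hk, epsilon=0.01)
    flags = F.flag_candidates(fcs, min_incubations=3)

    fcs.to_csv(ROOT / "fold_changes.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(flags)}).to_csv(
        ROOT / "fc_flagged.tsv", sep="\t", index=False)

    truth = json.loads((ROOT / "data" / "truth.json").read_text())
    markers = set(truth["marker_ko_ids"])
    flagged_markers = {g for g in flags if set(g.split("+")) & markers}
    baselines = fcs.groupby("incubation")["hk_baseline"].first()
    print(f"housekeeping baseline per incubation: "
          f"{ {k: round(v, 3) for k, v in baselines.items()} }")
    print(f"{len(flags)} genes exceed the baseline in >=3/4 incubations")
    print(f"planted markers flagged: {len(flagged_markers)}/{len(markers)}")


if __name__ == "__main__":
    main()
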