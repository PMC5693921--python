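"""Conservation scoring: maximal 200-nt sliding-window mean per lncRNA.

Reads the bedGraph-like track file written at simulation time, scores every
transcript, and applies the retention threshold (0.9).
"""

from pathlib import Path

import pandas as pd

from lncemt.conservation import max_window_conservation, read_conservation
from lncemt.synthetic import load_truth

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data" / "discovery"
OUT = ROOT / "results" / "tables"


def main() -> None:
    tracks = read_conservation(DATA / "conservation.tsv")
    truth = load_truth(DATA / "truth.json")
    scores = pd.Series(
        {tid: max_window_conservation(tr) for tid, tr in tracks.items()},
        name="max_window_score",
    ).sort_values(ascending=False)
    scores.rename_axis("lncrna").to_csv(OUT / "conservation_scores.tsv", sep="\t")
    conserved = scores[scores >= 0.9]
    print("conserved lncRNA (score >= 0.9):")
    for tid, s in conserved.items():
        mark = "*" if tid in truth.regulator_targets else " "
        print(f"  {tid}  {s:.3f} {mark}")
    print(f"({len(conserved)} of {len(scores)}; * = planted regulator)")


if __name__ == "__main__":
    main()
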