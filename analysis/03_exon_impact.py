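"""Summarize the exonic impact of optically validated SVs of a run.

Usage: python analysis/03_exon_impact.py --rundir runs/seed3
"""
from __future__ import annotations

import argparse
import json
from pathlib import Path


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rundir", required=True)
    args = ap.parse_args()

    rep = json.loads((Path(args.rundir) / "report.json").read_text())
    print("exons affected per line (validated SVs only):")
    for line, n in sorted(rep["exon_per_line"].items()):
        print(f"  {line}: {n}")
    print("overlaps by SV class (count / affected bp):")
    for cls in sorted(rep["exon_per_class_count"]):
        print(f"  {cls}: {rep['exon_per_class_count'][cls]} / "
              f"{rep['exon_per_class_bp'][cls]} bp")
    n_rows = sum(1 for _ in open(Path(args.rundir) / "exon_overlaps.tsv")) - 1
    print(f"total SV-exon overlap rows: {n_rows}")


if __name__ == "__main__":
    main()
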