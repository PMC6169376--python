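"""Summarize cross-line SV sharing and the line-relationship tree of a run.

Usage: python analysis/02_sharing_and_tree.py --rundir runs/seed3
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
    print("pairwise sharing (% of row line's loci also in column line):")
    lines = sorted(rep["sharing_pairwise"])
    print("\t" + "\t".join(lines))
    for a in lines:
        row = rep["sharing_pairwise"][a]
        print(a + "\t" + "\t".join(
            "-" if row[b] is None else f"{row[b]:.1f}" for b in lines))
    print(f"\nloci shared by all lines: {rep['shared_in_all']}")
    print(f"tree: {rep['newick']}")
    print("clade supports (BP/AU, percent):")
    for clade, s in sorted(rep["clade_supports"].items()):
        print(f"  {{{clade}}}: BP={s['bp']} AU={s['au']}")
    print(f"SV rate: {rep['rate']}")


if __name__ == "__main__":
    main()
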