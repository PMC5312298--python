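"""Discover the SPRY-M / NF1-M / PTEN-M co-expression modules.

Ranks every probe by Pearson correlation to each module's seed probe and
keeps the top N, then reports how much of the planted membership was
recovered.  Writes the membership table results/modules.tsv.
"""

import argparse
import json
from pathlib import Path

from rmpa.data_io import read_expression_matrix, read_probe_annotation
from rmpa.module_discovery import assemble_module, modules_membership_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--n-top", type=int, default=30)
    parser.add_argument("--out", type=Path, default=Path("results/modules.tsv"))
    args = parser.parse_args()

    expr = read_expression_matrix(args.cohort / "expression.tsv")
    annotation = read_probe_annotation(args.cohort / "annotation.tsv")
    truth = json.loads((args.cohort / "truth.json").read_text())

    modules = []
    for name, seed_gene in truth["seed_genes"].items():
        module = assemble_module(expr, annotation, [f"{seed_gene}_at"],
                                 n_top=args.n_top, name=name)
        planted = set(truth["module_members"][name])
        recovered = len((module.member_genes | module.seed_genes) & planted)
        print(f"{name}: {len(module.member_probes)} probes, "
              f"{recovered}/{len(planted)} planted genes recovered")
        modules.append(module)

    table = modules_membership_table(modules, annotation)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
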