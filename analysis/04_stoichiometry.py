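#!/usr/bin/env python
"""Why would one antibody bind two antigens more easily than another?

Rigid grafting on minimal IgG fixtures: superpose the (bound antigen +
light chain) substructure onto the free arm's light chain and count steric
clashes between the two antigen copies.  With well-separated arms the
virtual 2:1 complex is clash-free; with crowded arms the antigen copies
interpenetrate — the geometric signature of a disfavoured 2:1 stoichiometry.
Writes results/table_stoichiometry.csv.
"""

from pathlib import Path

import pandas as pd

from abaffinity.geometry import clash_report, graft_second_antigen
from abaffinity.synthetic import make_igg_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "table_stoichiometry.csv"


def main() -> None:
    rows = []
    for label, symmetric in (("open arms (C2)", True), ("crowded arms (25 deg)", False)):
        fixture = make_igg_fixture(symmetric=symmetric, seed=1)
        virtual, fit = graft_second_antigen(fixture, "G", "L", "M")
        report = clash_report(virtual, ["G"], ["X"], cutoff=2.5)
        rows.append(
            {
                "geometry": label,
                "fit_rmsd_A": round(fit.rmsd, 6),
                "clashing_atom_pairs": report.n_atom_pairs_below_cutoff,
                "min_antigen_antigen_distance_A": round(
                    report.min_interatomic_distance, 2
                ),
                "overlap_fraction": round(report.overlap_fraction, 3),
            }
        )
    df = pd.DataFrame(rows)
    OUT.parent.mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(df.to_string(index=False))
    print(
        "\nThe same rigid procedure, applied to the same antigen, is clash-free"
        "\non the open-arm geometry and heavily interpenetrating on the crowded"
        "\none: arm geometry alone can gate the 2:1 stoichiometry."
    )


if __name__ == "__main__":
    main()
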