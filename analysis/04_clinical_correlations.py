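"""Clinical correlation screen over the patient groups.

Spearman-correlates all 112 microstate features with VAS and ABC over
the 50 patients (MD + SV), applies Benjamini-Hochberg FDR at q = 0.05
separately per scale, and lists the surviving associations.
"""

from pathlib import Path

import pandas as pd

from bandstates import clinical_screen

OUT = Path("results")


def main() -> None:
    table = pd.read_csv(OUT / "feature_table.csv")
    res = clinical_screen(table)
    res.to_csv(OUT / "correlations.csv", index=False)
    sig = res[res.significant]
    print(f"{len(sig)} feature-scale pairs survive FDR (q < 0.05) out of {len(res)}")
    if not sig.empty:
        print(sig[["feature", "scale", "rho", "p", "q", "n"]].to_string(index=False))


if __name__ == "__main__":
    main()
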