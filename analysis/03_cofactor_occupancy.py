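"""Co-activator regulation classes and occupancy by TBS type.

Median-splits Taf1p (TFIID) and Spt20p (SAGA) occupancy into the four
regulation classes, checks recovery of the planted classes, and
summarizes SAGA/TFIID/Mot1p occupancy per TBS class: SAGA and Mot1p
ordered T5 > A5 > TATA-like while TFIID stays flat.
"""

from pathlib import Path

import pandas as pd

from tbpnoise.cofactor_classes import bin_turnover, classify_coactivator

ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "results" / "synthetic"
OUT = ROOT / "results"

if __name__ == "__main__":
    occupancy = pd.read_csv(SYN / "occupancy.tsv", sep="\t")
    truth = pd.read_csv(SYN / "promoter_truth.tsv", sep="\t")
    reg_truth = pd.read_csv(SYN / "regulation_truth.tsv", sep="\t").set_index(
        "gene_id"
    )
    classes = classify_coactivator(occupancy)
    classes.rename_axis("gene_id").reset_index().to_csv(
        OUT / "coactivator_classes.tsv", sep="\t", index=False
    )
    recovery = (
        classes["coactivator_class"]
        == reg_truth.loc[classes.index, "coactivator_class"]
    ).mean()
    print("class sizes:")
    print(classes["coactivator_class"].value_counts().to_string())
    print(f"planted co-activator class recovery: {recovery:.1%}")

    merged = occupancy.merge(
        truth[["gene_id", "tbs_class", "subset"]], on="gene_id"
    )
    medians = (
        merged.groupby(["tbs_class", "subset"])[["Spt20p", "Taf1p", "Mot1p", "TBP"]]
        .median()
        .round(3)
    )
    medians.to_csv(OUT / "occupancy_by_class.tsv", sep="\t")
    print("\noccupancy medians by TBS class (a.u.):")
    print(medians.to_string())

    turnover = pd.read_csv(SYN / "turnover.tsv", sep="\t").set_index("gene_id")[
        "turnover"
    ]
    bins = bin_turnover(turnover)
    bins.rename_axis("gene_id").reset_index().to_csv(
        OUT / "turnover_bins.tsv", sep="\t", index=False
    )
    lo, hi = bins.attrs["low_bin"], bins.attrs["high_bin"]
    print(
        f"\nturnover bins: low [{lo[0]:.3f}-{lo[1]:.3f}], "
        f"high ({hi[0]:.3f}-{hi[1]:.3f}] a.u."
    )
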