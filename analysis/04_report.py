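#!/usr/bin/env python
"""Summarize the finished analysis: per-feature significant-channel counts
with direction, and the group contrast of the 10-11 Hz relative spectrum."""

from pathlib import Path

import pandas as pd

from qeeg.stats import significant_channel_counts

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    comp = pd.read_csv(OUT / "comparison.csv")
    counts = significant_channel_counts(comp)
    arrow = {1: "ASD > TD", -1: "ASD < TD", 0: "-"}
    print("feature                 significant   direction")
    for _, row in counts.iterrows():
        print(f"  {row['feature']:<22} {row['n_significant']:>2d}/19        "
              f"{arrow[row['direction']]}")
    spectra_path = OUT / "spectra_per_hz.csv"
    if spectra_path.exists():
        sp = pd.read_csv(spectra_path)
        bin10 = sp[sp["bin_lo_hz"] == 10].groupby("group")["fraction"].mean()
        print(f"\nmean 10-11 Hz relative power: TD {bin10['TD']:.4f} "
              f"vs ASD {bin10['ASD']:.4f}")


if __name__ == "__main__":
    main()
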