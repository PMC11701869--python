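#!/usr/bin/env python
"""Count QC: detection filter, pOverA, outlier scan, size factors, VST.

Reads results/simulated/, removes undetected genes, applies the pOverA
low-expression filter (>= 10 counts in >= 25% of samples), scans for
outlier samples in VST principal-component space, computes median-of-ratios
size factors and the parametric dispersion trend, and writes the filtered
counts, dispersions and VST matrix to results/preprocessed/.
"""

from pathlib import Path

from frontloadseq import io, preprocess

IN = Path("results/simulated")
OUT = Path("results/preprocessed")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = io.read_count_matrix(IN / "counts.tsv")

    detected = preprocess.detect_filter(counts)
    filtered = preprocess.pover_a_filter(detected, p=0.25, a=10)
    print(
        f"{len(counts)} genes -> {len(detected)} detected -> "
        f"{len(filtered)} after pOverA(P=0.25, A=10)"
    )

    outliers = preprocess.flag_outlier_samples(filtered)
    if outliers:
        print(f"flagged outlier samples: {outliers}; refiltering without them")
        filtered = filtered.drop(columns=outliers)
        filtered = preprocess.pover_a_filter(
            preprocess.detect_filter(filtered), p=0.25, a=10
        )
    else:
        print("no outlier samples flagged")

    sf = preprocess.size_factors(filtered)
    trend = preprocess.estimate_dispersion_trend(filtered, sf)
    print(f"dispersion trend: {trend}")
    vst = preprocess.vst_transform(filtered, sf, trend)

    io.write_count_matrix(filtered, OUT / "filtered_counts.tsv")
    sf.to_csv(OUT / "size_factors.tsv", sep="\t")
    trend.trended().to_csv(OUT / "dispersions.tsv", sep="\t")
    vst.to_csv(OUT / "vst.tsv", sep="\t")
    print(f"wrote {len(filtered)} genes to {OUT}")


if __name__ == "__main__":
    main()
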