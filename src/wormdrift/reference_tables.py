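"""Published per-chromosome comparison tables for *C. elegans* lab assemblies.

These are the printed per-chromosome values from the published comparisons
of laboratory wild-type assemblies: the DLW-lab N2 Bristol vs. DLW CB4856
Hawaiian comparison, the DLW N2 Bristol vs. VC2010 Bristol comparison, and
the DLW CB4856 Hawaiian vs. Kim-lab CB4856 Hawaiian comparison.  They are
inputs to the summary arithmetic (totals rows, percent aligned), which the
reporting module recomputes from the per-chromosome cells rather than
trusting any pre-summed figure.

Counts are homozygous variant calls only.  Per-chromosome affected-bp
columns were not tabulated and are left as None.
"""

from __future__ import annotations

from .reporting import ChromosomeSummary

_CHROMS = ["I", "II", "III", "IV", "V", "X"]


def _rows(
    lengths_a, lengths_b, aligned, pct_syn, snps, indels, svs, hdrs
) -> list[ChromosomeSummary]:
    return [
        ChromosomeSummary(
            chrom=c,
            length_A=lengths_a[i],
            length_B=lengths_b[i],
            aligned_bases=aligned[i],
            pct_syntenic=pct_syn[i],
            n_snps=snps[i],
            n_indels=indels[i],
            indel_bp=None,
            n_svs=svs[i],
            sv_bp=None,
            n_hdrs=hdrs[i],
            hdr_bp=None,
        )
        for i, c in enumerate(_CHROMS)
    ]


def bristol_vs_hawaiian() -> list[ChromosomeSummary]:
    """DLW N2 Bristol (reference) vs. DLW CB4856 Hawaiian, per chromosome."""
    return _rows(
        lengths_a=[15_114_068, 15_311_845, 13_819_453, 17_493_838, 20_953_657, 17_739_129],
        lengths_b=[15_045_644, 15_257_363, 13_206_755, 17_183_882, 20_547_529, 17_584_915],
        aligned=[15_100_574, 15_303_320, 13_222_676, 17_330_119, 20_947_147, 17_738_394],
        pct_syn=[93.31, 88.56, 90.61, 95.42, 87.04, 98.73],
        snps=[30_394, 48_365, 29_881, 30_497, 87_300, 19_861],
        indels=[11_460, 13_716, 10_530, 11_221, 20_063, 6_799],
        svs=[863, 808, 649, 619, 925, 470],
        hdrs=[185, 270, 165, 138, 356, 60],
    )


def bristol_vs_vc2010() -> list[ChromosomeSummary]:
    """DLW N2 Bristol (reference) vs. VC2010 Bristol, per chromosome."""
    return _rows(
        lengths_a=[15_114_068, 15_311_845, 13_819_453, 17_493_838, 20_953_657, 17_739_129],
        lengths_b=[15_331_301, 15_525_148, 14_108_536, 17_759_200, 21_243_235, 18_110_855],
        aligned=[15_108_942, 15_310_622, 13_819_294, 17_492_076, 20_852_291, 17_738_432],
        pct_syn=[98.83, 99.83, 99.47, 99.12, 99.05, 99.50],
        snps=[169, 124, 164, 209, 280, 216],
        indels=[150, 261, 210, 262, 378, 267],
        svs=[113, 134, 83, 228, 175, 164],
        hdrs=[8, 14, 10, 21, 24, 11],
    )


def hawaiian_vs_kim() -> list[ChromosomeSummary]:
    """DLW CB4856 Hawaiian (reference) vs. Kim CB4856 Hawaiian, per chromosome."""
    return _rows(
        lengths_a=[15_045_644, 15_257_363, 13_206_755, 17_183_882, 20_547_529, 17_584_915],
        lengths_b=[15_528_896, 15_813_191, 14_110_336, 17_985_219, 21_389_866, 18_073_349],
        aligned=[14_620_886, 14_680_704, 12_451_582, 16_482_840, 19_427_050, 17_371_269],
        pct_syn=[94.91, 92.38, 93.01, 89.28, 89.24, 96.10],
        snps=[60, 52, 71, 108, 135, 115],
        indels=[240, 190, 175, 242, 238, 213],
        svs=[148, 274, 194, 626, 660, 168],
        hdrs=[19, 70, 25, 100, 144, 12],
    )
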