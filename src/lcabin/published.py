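"""Published summary counts from a ten-dataset AnnoTree vs NCBI-nr study.

These are the printed per-dataset alignment counts and pooled
per-classification assignment counts from a published comparison of
DIAMOND+MEGAN runs against the AnnoTree protein database and against the
prokaryotic part of NCBI-nr. They serve as worked-example inputs for the
summary arithmetic (assignment rates, ratios, rank correlation); the
package recomputes the derived percentages from these counts rather than
storing them.
"""

from __future__ import annotations

__all__ = [
    "DATASET_ALIGNMENTS",
    "TOTAL_READS",
    "CLASSIFICATION_ASSIGNED",
    "MAPPED_ACCESSIONS",
]

#: Per-dataset (total_reads, reads aligned in the AnnoTree run, reads
#: aligned in the NCBI-nr run).
DATASET_ALIGNMENTS: dict[str, tuple[int, int, int]] = {
    "River1": (646_178, 410_118, 406_913),
    "River2": (129_753_222, 90_535_941, 88_403_713),
    "Seagrass": (98_260_754, 36_053_215, 33_717_202),
    "Skin": (22_827_626, 13_403_495, 14_122_490),
    "Stool": (33_214_614, 29_132_562, 30_101_313),
    "Soil": (97_595_185, 10_992_188, 7_264_223),
    "ThermalPools": (52_908_626, 15_751_382, 16_625_446),
    "Bioreactor1": (99_998_110, 73_151_916, 72_806_515),
    "Bioreactor2": (44_258_996, 36_608_649, 37_477_641),
    "Bioreactor3": (694_827, 613_958, 616_536),
}

#: Pooled read total over the ten datasets.
TOTAL_READS: int = 580_158_138

#: Pooled assigned-read counts per classification:
#: classification -> (AnnoTree run, NCBI-nr run).
CLASSIFICATION_ASSIGNED: dict[str, tuple[int, int]] = {
    "Taxonomy": (305_150_157, 297_539_333),
    "GTDB": (303_770_449, 282_269_816),
    "EC": (78_874_545, 76_552_285),
    "EGGNOG": (95_932_149, 87_131_284),
    "INTERPRO2GO": (142_250_858, 143_885_580),
    "KEGG": (209_371_499, 123_130_673),
    "SEED": (102_452_692, 100_615_086),
}

#: Reference-database coverage: classification -> (NCBI-nr accessions
#: with a class, AnnoTree accessions with a class).
MAPPED_ACCESSIONS: dict[str, tuple[int, int]] = {
    "Taxonomy": (182_329_414, 106_052_079),
    "GTDB": (126_956_422, 106_052_079),
    "EC": (4_501_593, 2_962_187),
    "EGGNOG": (4_274_800, 3_506_041),
    "INTERPRO2GO": (19_748_423, 11_069_757),
    "KEGG": (8_218_708, 56_577_432),
    "SEED": (31_117_272, 16_183_436),
}


def aligned_totals() -> tuple[int, int, int]:
    """(total reads, AnnoTree aligned, NCBI-nr aligned) summed over datasets."""
    total = sum(v[0] for v in DATASET_ALIGNMENTS.values())
    annotree = sum(v[1] for v in DATASET_ALIGNMENTS.values())
    ncbi = sum(v[2] for v in DATASET_ALIGNMENTS.values())
    return total, annotree, ncbi
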