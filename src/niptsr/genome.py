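"""Reference chromosome sizes used by the synthetic-panel generator.

Lengths are GRCh38 primary-assembly autosome lengths in base pairs.  Only
autosomes are listed: the capture panel and the rearrangement analysis are
autosomal (sex chromosomes are excluded from haplotype dosage because the
maternal X mixture is not a two-haplotype problem in male pregnancies).
"""

from __future__ import annotations

GRCH38_AUTOSOMES: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
}

#: Acrocentric autosomes (short arms carry only rDNA repeats); the only
#: chromosomes on which a Robertsonian fusion can occur.
ACROCENTRIC = frozenset({"13", "14", "15", "21", "22"})


def is_acrocentric(chrom: str) -> bool:
    """True if ``chrom`` names an acrocentric autosome ('14' or 'chr14')."""
    return chrom.removeprefix("chr") in ACROCENTRIC
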