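"""Packaged defaults and YAML configuration loading.

The packaged spacer backbone is a synthetic 280 bp sequence (a stand-in for
the bacteriophage-lambda spacer used historically for padlock-probe
precursors).  It is free of MlyI and BsaI recognition sites on both strands
and carries the two post-capture amplification primer landing sites
("linkers") at its ends, in the orientation required so that amplification
off a captured circle yields linker -> arm -> insert -> arm -> linker.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

from .sequence_model import MLYI, BSAI, RestrictionEnzyme, revcomp

# Post-capture amplification primer landing sites (linkers), and the extra
# bases by which the two sequencing primers extend past them.  The read-1
# sequencing primer is LINK_F + READ1_EXT, the read-2 primer LINK_R +
# READ2_EXT, so sequencing reads start exactly at the arm boundary.
LINK_F = "GATCTTAACCCTCACTAAAGGGAGGC"
LINK_R = "GATCCCAATTTAGGTGACACTATAGGCGG"
READ1_EXT = "GCGCC"
READ2_EXT = "CCGC"

# Illumina flow-cell adaptors.
P5 = "AATGATACGGCGACCACCGAGATCTACAC"
P7 = "CAAGCAGAAGACGGCATACGAGAT"

#: Synthetic 280 bp spacer backbone (see module docstring).  Layout:
#: revcomp(READ2_EXT) + revcomp(LINK_R) + 216 nt filler + LINK_F + READ1_EXT.
DEFAULT_BACKBONE = (
    "GCGGCCGCCTATAGTGTCACCTAAATTGGGATCAATTATGTGTAGAATTTCACTAATACTTCAACGGC"
    "GTTGCATGCTCATTACAAACTACCGCTATAGTGAACGCGCGATTGGCATCAATTTTCGGTCGGTATAA"
    "TTGGGTAGCGCGGAGGTTGGTATTGTAATCTGTCTGCCGTGTTCACTTCACGGCGACCTGACAGTGCA"
    "ACTCCACGGTCCACGTTTTCTCACTCTATACAGAGGTAACTAAGAGATCTTAACCCTCACTAAAGGGA"
    "GGCGCGCC"
)
assert len(DEFAULT_BACKBONE) == 280
assert DEFAULT_BACKBONE.endswith(LINK_F + READ1_EXT)
assert DEFAULT_BACKBONE.startswith(revcomp(LINK_R + READ2_EXT))

# Amplicon reference flanks contributed by the probe backbone: the portion
# of the backbone that ends up inside the amplified product on each side of
# the captured target.
AMPLICON_FLANK_F = LINK_F + READ1_EXT
AMPLICON_FLANK_R = revcomp(READ2_EXT) + revcomp(LINK_R)

DEFAULTS: dict[str, Any] = {
    "enzymes": {
        "MlyI": {"recognition": "GAGTC", "top_cut_offset": 5, "bottom_cut_offset": 5},
        "BsaI": {"recognition": "GGTCTC", "top_cut_offset": 1, "bottom_cut_offset": 5},
    },
    "probe": {
        "arm_len": 25,          # mid-range of the allowed 18-28
        "arm_min": 18,
        "arm_max": 28,
        "max_gap": 550,         # maximum gap-fill length
        "tile_overlap": 50,
        "primer_len": 60,
        "mly_spacer": "CATCA",  # 5 nt: puts the blunt MlyI cut at the arm boundary
        "bsa_spacer": "A",      # 1 nt: BsaI 4-nt overhang falls inside the arm
        "gc_threshold": 0.65,
        "gc_max": 0.80,
        "weight_max": 4.0,
    },
    "capture": {
        "mode": "clpp",
        "p0": 0.9,
        "gc_threshold": 0.65,
        "gc_halving": 0.15,     # GC excess over threshold that halves efficiency
        "molecules_per_copy": 10,
    },
    "library": {
        "r1_len": 175,
        "r2_len": 150,
        "index_len": 6,
        "mode": "rpe",
        "pcr_error_rate": 0.0,
    },
    "processing": {
        "evalue": 1e-6,
        "mapq_min": 30,
        "baseq_min": 20,
        "min_depth": 20,
        "het_band": [0.25, 0.75],
        "hom_threshold": 0.85,
    },
    "cnv": {
        "lowess_frac": 0.3,
        "bin_size": 200,
        "loss_max": 0.7,
        "gain_min": 1.35,
        "min_consecutive": 2,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as handle:
        user = yaml.safe_load(handle) or {}
    return _merge(DEFAULTS, user)


def enzymes_from_config(config: dict) -> dict[str, RestrictionEnzyme]:
    return {
        name: RestrictionEnzyme(
            name, spec["recognition"], spec["top_cut_offset"], spec["bottom_cut_offset"]
        )
        for name, spec in config["enzymes"].items()
    }


DEFAULT_ENZYMES = (MLYI, BSAI)
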