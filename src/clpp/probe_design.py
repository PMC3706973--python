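"""Design of cLPP precursors and functional probe duplexes for a panel.

A complementary long padlock probe (cLPP) is released from a ~350 bp PCR
precursor by simultaneous MlyI/BsaI digestion.  The precursor is built from
two primers: the forward primer carries the MlyI site, a 5 nt spacer, the
downstream capture arm and a backbone anneal region; the reverse primer
carries the BsaI site, a 1 nt spacer, the reverse complement of the
upstream arm, and a backbone anneal region.  The spacers are sized so that
the blunt MlyI cut lands exactly at the arm boundary and the BsaI 4 nt
5' overhang falls inside the arm: after digestion the functional duplex
terminates in target sequence only.

Strand layout of the functional duplex for a target [start, end):

    top:    5'-arm_down  backbone  arm_up[: -4]-3'
    bottom: 5'-rc(arm_up)  rc(backbone)  rc(arm_down)-3'

Each single strand is itself a padlock probe: the bottom strand's 3'
terminus anneals at the downstream arm on the sense genomic strand and is
extended across the gap (capturing the sense strand); the top strand does
the mirror-image job on the antisense strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import config as cfg
from .sequence_model import (
    BSAI,
    MLYI,
    Duplex,
    GenomicInterval,
    RestrictionEnzyme,
    digest,
    find_sites,
    gc_content,
    revcomp,
)


class DesignError(ValueError):
    """A target that cannot be designed against (reported, then skipped)."""


class ProbeValidationError(RuntimeError):
    """Digestion of a precursor did not reproduce arm-terminated probe ends."""


@dataclass(frozen=True)
class ArmPair:
    """The two capture arms flanking a gap-fill target."""

    arm_up: str
    arm_down: str
    up_interval: GenomicInterval
    down_interval: GenomicInterval


@dataclass
class ProbeDesign:
    """Everything needed downstream for one designed target."""

    name: str
    target: GenomicInterval
    arms: ArmPair
    forward_primer: str
    reverse_primer: str
    precursor: Duplex
    functional_probe: Duplex
    insert_seq: str
    abundance_weight: float = 1.0
    gc: float = 0.0

    @property
    def amplicon_seq(self) -> str:
        """Amplicon reference record: probe-derived flanks + arms + insert."""
        return (
            cfg.AMPLICON_FLANK_F
            + self.arms.arm_up
            + self.insert_seq
            + self.arms.arm_down
            + cfg.AMPLICON_FLANK_R
        )

    @property
    def insert_offset(self) -> int:
        """Start of the insert within the amplicon record."""
        return len(cfg.AMPLICON_FLANK_F) + len(self.arms.arm_up)


def select_arms(
    reference: Mapping[str, str],
    target: GenomicInterval,
    arm_len: int,
    enzymes: Sequence[RestrictionEnzyme] = (MLYI, BSAI),
    arm_min: int = 18,
    arm_max: int = 28,
) -> ArmPair:
    """Copy the two capture arms from the reference flanks of ``target``.

    Arms are exact reference slices abutting the target with no gap or
    overlap.  Raises :class:`ValueError` for an out-of-range ``arm_len`` and
    :class:`DesignError` when the flanks do not exist or an arm contains an
    internal restriction site (which would be destroyed during trimming).
    """
    if not (arm_min <= arm_len <= arm_max):
        raise ValueError(f"arm_len {arm_len} outside [{arm_min}, {arm_max}]")
    contig_seq = reference[target.contig]
    if target.start - arm_len < 0 or target.end + arm_len > len(contig_seq):
        raise DesignError(f"target {target} too close to contig edge for arms")
    arm_up = contig_seq[target.start - arm_len : target.start]
    arm_down = contig_seq[target.end : target.end + arm_len]
    for arm, label in ((arm_up, "upstream"), (arm_down, "downstream")):
        for enzyme in enzymes:
            if find_sites(arm, enzyme):
                raise DesignError(
                    f"{label} arm of {target} contains a {enzyme.name} site"
                )
    return ArmPair(
        arm_up,
        arm_down,
        GenomicInterval(target.contig, target.start - arm_len, target.start),
        GenomicInterval(target.contig, target.end, target.end + arm_len),
    )


def build_precursor(
    arms: ArmPair,
    backbone: str = cfg.DEFAULT_BACKBONE,
    enzymes: Sequence[RestrictionEnzyme] = (MLYI, BSAI),
    primer_len: int = 60,
    mly_spacer: str = "CATCA",
    bsa_spacer: str = "A",
    min_anneal: int = 18,
) -> tuple[str, str, Duplex]:
    """Primers and simulated PCR precursor for one arm pair.

    Returns ``(forward_primer, reverse_primer, precursor)``.  The precursor
    carries exactly one MlyI and one BsaI site; a backbone containing either
    recognition sequence is rejected.
    """
    mly, bsa = enzymes
    for enzyme in enzymes:
        if find_sites(backbone, enzyme):
            raise DesignError(f"backbone contains a {enzyme.name} site")
    if len(mly_spacer) != mly.top_cut_offset:
        raise ValueError("MlyI spacer must equal the enzyme's cut offset")
    if len(bsa_spacer) != bsa.top_cut_offset:
        raise ValueError("BsaI spacer must equal the enzyme's top cut offset")
    anneal_f = max(min_anneal, primer_len - len(mly.recognition) - len(mly_spacer) - len(arms.arm_down))
    anneal_r = max(min_anneal, primer_len - len(bsa.recognition) - len(bsa_spacer) - len(arms.arm_up))
    anneal_f = min(anneal_f, len(backbone) // 2)
    anneal_r = min(anneal_r, len(backbone) // 2)
    forward = mly.recognition + mly_spacer + arms.arm_down + backbone[:anneal_f]
    reverse = (
        bsa.recognition + bsa_spacer + revcomp(arms.arm_up) + revcomp(backbone[-anneal_r:])
    )
    sense = (
        mly.recognition
        + mly_spacer
        + arms.arm_down
        + backbone
        + arms.arm_up
        + revcomp(bsa_spacer)
        + revcomp(bsa.recognition)
    )
    for enzyme in enzymes:
        n_sites = len(find_sites(sense, enzyme))
        if n_sites != 1:
            raise DesignError(
                f"precursor has {n_sites} {enzyme.name} sites (need exactly 1)"
            )
    return forward, reverse, Duplex(sense)


def make_functional_probe(
    precursor: Duplex,
    arms: ArmPair,
    enzymes: Sequence[RestrictionEnzyme] = (MLYI, BSAI),
    name: str = "",
) -> Duplex:
    """Trim the precursor with both enzymes and validate the middle fragment.

    The middle digestion fragment is returned with 5'-phosphorylated ends;
    its strand termini must equal the capture arms (allowing the 4 nt BsaI
    overhang recession on the top strand).
    """
    for enzyme in enzymes:
        n_sites = len(find_sites(precursor.sense, enzyme))
        if n_sites != 1:
            raise DesignError(
                f"precursor{' ' + name if name else ''} has {n_sites} "
                f"{enzyme.name} sites (need exactly 1)"
            )
    fragments = digest(precursor, list(enzymes))
    if len(fragments) != 3:
        raise ProbeValidationError(
            f"digestion of precursor{' ' + name if name else ''} gave "
            f"{len(fragments)} fragments, expected 3"
        )
    probe = fragments[1]
    ok = (
        probe.sense.startswith(arms.arm_down)
        and probe.sense.endswith(arms.arm_up)
        and probe.top.startswith(arms.arm_down)
        and probe.bottom.startswith(revcomp(arms.arm_up))
        and probe.bottom.endswith(revcomp(arms.arm_down))
        and arms.arm_up.startswith(probe.top[len(probe.top) - (len(arms.arm_up) - 4):] )
        and probe.phos_top5
        and probe.phos_bot5
    )
    if not ok:
        raise ProbeValidationError(
            f"functional probe termini do not match arms for design {name or '<unnamed>'}"
        )
    return probe


def tile_target(
    target: GenomicInterval, max_gap: int = 550, overlap: int = 50
) -> list[GenomicInterval]:
    """Split an oversize target into the minimum number of overlapping tiles.

    Targets no longer than ``max_gap`` are returned unchanged.  Tiles share
    ``overlap`` bases with their neighbours and jointly cover the target.
    """
    if not max_gap > overlap >= 0:
        raise ValueError("need max_gap > overlap >= 0")
    if target.length <= max_gap:
        return [target]
    n = math.ceil((target.length - overlap) / (max_gap - overlap))
    # Distribute lengths as evenly as possible while keeping every
    # neighbour overlap exactly at the configured value.
    total = target.length + (n - 1) * overlap
    base, extra = divmod(total, n)
    lengths = [base + (1 if i < extra else 0) for i in range(n)]
    tiles = []
    start = target.start
    for i, tile_len in enumerate(lengths):
        tiles.append(
            GenomicInterval(
                target.contig, start, start + tile_len, f"{target.name}.{i + 1}"
            )
        )
        start += tile_len - overlap
    return tiles


def assign_weight(
    gc: float,
    gc_threshold: float = 0.65,
    gc_max: float = 0.80,
    weight_max: float = 4.0,
) -> float:
    """Probe abundance weight as a function of target GC content.

    1.0 at or below ``gc_threshold``, then a linear ramp reaching
    ``weight_max`` at ``gc_max`` (clamped above).  Monotone non-decreasing.
    """
    if gc <= gc_threshold:
        return 1.0
    frac = min(gc - gc_threshold, gc_max - gc_threshold) / (gc_max - gc_threshold)
    return 1.0 + (weight_max - 1.0) * frac


def assign_weights(designs: Sequence[ProbeDesign], **policy) -> None:
    """Set ``abundance_weight`` on each design from its GC content."""
    if not designs:
        raise ValueError("no designs to weight")
    for design in designs:
        design.abundance_weight = assign_weight(design.gc, **policy)


@dataclass
class PanelReferences:
    """Reference files emitted for a designed panel."""

    amplicons: list[tuple[str, str]]
    inserts: list[tuple[str, str]]
    targets: list[GenomicInterval]
    meta: pd.DataFrame  # one row per design: coordinates and layout offsets

    def write(self, outdir) -> None:
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(outdir / "amplicons.fa", self.amplicons)
        io.write_fasta(outdir / "inserts.fa", self.inserts)
        io.write_bed(outdir / "targets.bed", self.targets)
        self.meta.to_csv(outdir / "panel_meta.tsv", sep="\t", index=False)


def build_references(designs: Sequence[ProbeDesign]) -> PanelReferences:
    """Amplicon and insert-only reference records plus a target BED.

    Records are ordered by genomic coordinate; duplicate design names are an
    error.  Per design the insert-only record length equals the amplicon
    length minus the two arms and the probe-derived flanks.
    """
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate design names: {dupes}")
    ordered = sorted(designs, key=lambda d: (d.target.contig, d.target.start))
    meta = pd.DataFrame(
        {
            "name": [d.name for d in ordered],
            "contig": [d.target.contig for d in ordered],
            "start": [d.target.start for d in ordered],
            "end": [d.target.end for d in ordered],
            "arm_up_len": [len(d.arms.arm_up) for d in ordered],
            "arm_down_len": [len(d.arms.arm_down) for d in ordered],
            "flank_f_len": [len(cfg.AMPLICON_FLANK_F)] * len(ordered),
            "flank_r_len": [len(cfg.AMPLICON_FLANK_R)] * len(ordered),
            "insert_offset": [d.insert_offset for d in ordered],
            "insert_len": [len(d.insert_seq) for d in ordered],
            "weight": [d.abundance_weight for d in ordered],
            "gc": [d.gc for d in ordered],
        }
    )
    return PanelReferences(
        amplicons=[(d.name, d.amplicon_seq) for d in ordered],
        inserts=[(d.name, d.insert_seq) for d in ordered],
        targets=[
            GenomicInterval(d.target.contig, d.target.start, d.target.end, d.name)
            for d in ordered
        ],
        meta=meta,
    )


def design_panel(
    reference: Mapping[str, str],
    targets: Sequence[GenomicInterval],
    backbone: str = cfg.DEFAULT_BACKBONE,
    config: dict | None = None,
    enzymes: Sequence[RestrictionEnzyme] = (MLYI, BSAI),
    snv_mask: Sequence[GenomicInterval] = (),
) -> tuple[list[ProbeDesign], pd.DataFrame]:
    """Design probes for every target, tiling oversize ones.

    Per sub-target a single greedy pass varies the arm length by up to
    +/-3 nt around the default to dodge internal restriction sites.  Targets
    that still fail are reported with status ``failed`` and skipped; arms
    overlapping a masked SNV produce a warning status but are kept.
    Returns the list of successful designs and a per-target report.
    """
    conf = (config or cfg.load_config())["probe"]
    report_rows = []
    designs: list[ProbeDesign] = []
    for target in targets:
        if not target.name:
            target = GenomicInterval(
                target.contig, target.start, target.end,
                f"{target.contig}_{target.start}_{target.end}",
            )
        for tile in tile_target(target, conf["max_gap"], conf["tile_overlap"]):
            row = {
                "name": tile.name, "contig": tile.contig,
                "start": tile.start, "end": tile.end, "status": "ok", "detail": "",
            }
            design = None
            last_err = None
            for delta in (0, 1, -1, 2, -2, 3, -3):
                arm_len = conf["arm_len"] + delta
                if not (conf["arm_min"] <= arm_len <= conf["arm_max"]):
                    continue
                try:
                    arms = select_arms(
                        reference, tile, arm_len, enzymes,
                        conf["arm_min"], conf["arm_max"],
                    )
                    fwd, rev, precursor = build_precursor(
                        arms, backbone, enzymes,
                        conf["primer_len"], conf["mly_spacer"], conf["bsa_spacer"],
                    )
                    probe = make_functional_probe(precursor, arms, enzymes, tile.name)
                except (DesignError, ProbeValidationError) as err:
                    last_err = err
                    continue
                insert = reference[tile.contig][tile.start : tile.end]
                gc = gc_content(arms.arm_up + insert + arms.arm_down)
                design = ProbeDesign(
                    name=tile.name, target=tile, arms=arms,
                    forward_primer=fwd, reverse_primer=rev,
                    precursor=precursor, functional_probe=probe,
                    insert_seq=insert, gc=gc,
                )
                break
            if design is None:
                row["status"] = "failed"
                row["detail"] = str(last_err)
                report_rows.append(row)
                continue
            if any(
                m.contig == tile.contig
                and (m.start < design.arms.up_interval.end and m.end > design.arms.up_interval.start
                     or m.start < design.arms.down_interval.end and m.end > design.arms.down_interval.start)
                for m in snv_mask
            ):
                row["status"] = "warn_snv_in_arm"
            design.abundance_weight = assign_weight(
                design.gc, conf["gc_threshold"], conf["gc_max"], conf["weight_max"]
            )
            row["gc"] = round(design.gc, 4)
            row["weight"] = round(design.abundance_weight, 4)
            designs.append(design)
            report_rows.append(row)
    return designs, pd.DataFrame(report_rows)


def write_panel(designs: Sequence[ProbeDesign], report: pd.DataFrame, outdir) -> PanelReferences:
    """Write primers.tsv, probes.fa, reference files and the design report."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = build_references(designs)
    refs.write(outdir)
    pd.DataFrame(
        {
            "name": [d.name for d in designs],
            "forward_primer": [d.forward_primer for d in designs],
            "reverse_primer": [d.reverse_primer for d in designs],
        }
    ).to_csv(outdir / "primers.tsv", sep="\t", index=False)
    io.write_fasta(
        outdir / "probes.fa",
        [(f"{d.name}/top", d.functional_probe.top) for d in designs]
        + [(f"{d.name}/bottom", d.functional_probe.bottom) for d in designs],
    )
    report.to_csv(outdir / "design_report.tsv", sep="\t", index=False)
    return refs
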