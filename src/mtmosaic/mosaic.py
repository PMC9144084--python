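"""Mosaic-genome annotation, recency classification, diagnostic markers,
and the end-to-end pipeline.

A genome is *mosaic* when it carries recombinant fragments of distinct
ancestry on a conspecific backbone.  Recency is encoded purely as the
count of recombinant-versus-minor-parent mismatches inside each fragment:
zero mismatches means the transferred copy is still identical to the
donor lineage (and, notably, is the signature expected of either a very
recent transfer or a PCR-jumping artifact), while accumulated mismatches
indicate time since transfer and rule out a simple PCR artifact.  No
molecular-clock dating is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignio import (
    AlignmentError,
    MultipleAlignment,
    RegionSpec,
    delete_regions,
    write_fasta,
)
from .diversity import (
    HDRegion,
    detect_hd_regions,
    distance_matrix,
    nj_tree,
    nucleotide_diversity,
    sliding_profile,
)
from .recomb import (
    ConfigurationError,
    RecombConfig,
    RecombinationEvent,
    call_events,
    phi_test,
)

__all__ = [
    "MosaicAnnotation",
    "RecencyCall",
    "DiagnosticMarker",
    "PipelineConfig",
    "PipelineReport",
    "annotate_mosaic",
    "count_fragment_mismatches",
    "extract_markers",
    "hd_regions_from_pairs",
    "run_pipeline",
]

log = logging.getLogger("mtmosaic")


@dataclass(frozen=True)
class MosaicAnnotation:
    """Ordered, non-overlapping recombination events on one genome."""

    genome_id: str
    backbone_id: str  # major parent of the genome's backbone
    events: tuple[RecombinationEvent, ...]
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class RecencyCall:
    """Mismatch-based recency classification of one event."""

    event: RecombinationEvent
    mismatches: int
    positions: tuple[int, ...]  # 1-based alignment columns of the mismatches
    call: str  # "identical" | "diverged"
    note: str = ""


@dataclass(frozen=True)
class DiagnosticMarker:
    """A recombinant fragment usable to genotype hybrids."""

    region: RegionSpec
    recombinant_id: str
    minor_parent_id: str
    identity_fraction: float
    diagnostic_identical: bool


def annotate_mosaic(
    events: Sequence[RecombinationEvent], genome_id: str, backbone_id: str
) -> MosaicAnnotation:
    """Sort events by begin; merge overlaps keeping the smaller corrected p.

    Every event must reference ``genome_id``; the discarded member of an
    overlapping pair is recorded in the annotation notes.
    """
    for ev in events:
        if ev.recombinant_id != genome_id:
            raise ConfigurationError(
                f"event on {ev.recombinant_id!r} cannot annotate genome {genome_id!r}"
            )
    ordered = sorted(events, key=lambda e: (e.begin, e.p_values.get("corrected", 1.0)))
    kept: list[RecombinationEvent] = []
    notes: list[str] = []
    for ev in ordered:
        if kept and ev.begin <= kept[-1].end:
            prev = kept[-1]
            if ev.p_values.get("corrected", 1.0) < prev.p_values.get("corrected", 1.0):
                kept[-1] = ev
                dropped = prev
            else:
                dropped = ev
            notes.append(
                f"overlapping event {dropped.begin}-{dropped.end} "
                f"(minor {dropped.minor_parent_id}) discarded in favour of "
                f"{kept[-1].begin}-{kept[-1].end}"
            )
        else:
            kept.append(ev)
    return MosaicAnnotation(
        genome_id=genome_id,
        backbone_id=backbone_id,
        events=tuple(kept),
        notes=tuple(notes),
    )


def count_fragment_mismatches(
    aln: MultipleAlignment, event: RecombinationEvent
) -> RecencyCall:
    """Recombinant-vs-minor-parent differences inside [begin, end]."""
    bm = aln.base_mask()
    ia = aln.index_of(event.recombinant_id)
    ib = aln.index_of(event.minor_parent_id)
    sl = slice(event.begin - 1, event.end)
    comp = bm[ia, sl] & bm[ib, sl]
    dif = (aln.matrix[ia, sl] != aln.matrix[ib, sl]) & comp
    positions = tuple(int(p) + event.begin for p in np.flatnonzero(dif))
    n = len(positions)
    return RecencyCall(
        event=event,
        mismatches=n,
        positions=positions,
        call="identical" if n == 0 else "diverged",
        note="" if n else "fragment still an exact copy of the minor parent",
    )


def extract_markers(
    annotations: Sequence[MosaicAnnotation], aln: MultipleAlignment
) -> list[DiagnosticMarker]:
    """One marker per annotated event; full-identity fragments are flagged
    diagnostic-identical."""
    if not annotations:
        raise ConfigurationError("extract_markers requires at least one annotation")
    bm = aln.base_mask()
    out = []
    for ann in annotations:
        for ev in ann.events:
            ia = aln.index_of(ev.recombinant_id)
            ib = aln.index_of(ev.minor_parent_id)
            sl = slice(ev.begin - 1, ev.end)
            comp = bm[ia, sl] & bm[ib, sl]
            n = int(comp.sum())
            same = int(((aln.matrix[ia, sl] == aln.matrix[ib, sl]) & comp).sum())
            ident = same / n if n else 0.0
            out.append(
                DiagnosticMarker(
                    region=RegionSpec(ev.begin, ev.end, ann.genome_id),
                    recombinant_id=ev.recombinant_id,
                    minor_parent_id=ev.minor_parent_id,
                    identity_fraction=ident,
                    diagnostic_identical=(ident == 1.0),
                )
            )
    return out


def hd_regions_from_pairs(
    aln: MultipleAlignment,
    ids: Sequence[str],
    window: int = 100,
    step: int = 25,
    fold_threshold: float = 5.0,
    min_windows: int | None = None,
    absolute_floor: float = 0.02,
) -> list[HDRegion]:
    """Distinct high-divergence regions over all pairwise dxy profiles.

    Mirrors reading a panel of pairwise sliding-window plots: each
    unordered pair of ``ids`` is scanned separately and overlapping
    regions from different pairs are merged (keeping the highest peak).

    On a two-sequence profile at conspecific divergence the median window
    value is zero, so only the absolute floor thresholds the scan and a
    chance cluster of a few mutations can clear it.  Such a point cluster
    can never stay elevated for more than ``window // step`` consecutive
    windows, whereas a genuine divergent fragment (>= window columns at
    interspecific divergence) spans more; the default minimum run length
    of ``window // step + 1`` candidate windows separates the two.
    """
    if min_windows is None:
        min_windows = window // step + 1
    found: list[HDRegion] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            prof = sliding_profile(aln.subset([ids[i], ids[j]]), "dxy", window, step)
            found.extend(
                detect_hd_regions(prof, fold_threshold, min_windows, absolute_floor)
            )
    found.sort(key=lambda r: (r.start, r.end))
    merged: list[HDRegion] = []
    for reg in found:
        if merged and reg.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = HDRegion(
                start=prev.start,
                end=max(prev.end, reg.end),
                peak_midpoint=(
                    prev.peak_midpoint
                    if prev.peak_value >= reg.peak_value
                    else reg.peak_midpoint
                ),
                peak_value=max(prev.peak_value, reg.peak_value),
                background=min(prev.background, reg.background),
            )
        else:
            merged.append(reg)
    return merged


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs in one place.  Window geometry defaults to
    100-column windows moved in 25-column steps; HD calling uses a 5x
    fold-over-median threshold with a 0.02 absolute floor."""

    window: int = 100
    step: int = 25
    phi_w: int = 100
    phi_permutations: int = 100_000
    maxchi_k: int = 30
    maxchi_permutations: int = 1000
    maxchi_flank: int = 1500
    alpha: float = 0.05
    fold_threshold: float = 5.0
    min_windows: int = 2
    absolute_floor: float = 0.02
    n_bootstrap: int = 1000
    deletion_policy: str = "pairwise"
    seed: int = 0

    def recomb(self) -> RecombConfig:
        return RecombConfig(
            window=self.window,
            step=self.step,
            phi_w=self.phi_w,
            phi_permutations=self.phi_permutations,
            maxchi_k=self.maxchi_k,
            maxchi_permutations=self.maxchi_permutations,
            maxchi_flank=self.maxchi_flank,
            alpha=self.alpha,
            seed=self.seed,
        )


@dataclass
class PipelineReport:
    """Machine-readable bundle of every pipeline stage's output."""

    config: PipelineConfig
    candidates: tuple[str, ...]
    groups: Mapping[str, str]
    pi_candidates: Mapping[str, float]
    pi_candidates_hd_excluded: Mapping[str, float] | None
    hd_regions_pi: tuple[HDRegion, ...]
    hd_regions_pairwise: tuple[HDRegion, ...]
    phi_global: Mapping[str, object]
    events: tuple[RecombinationEvent, ...]
    annotations: tuple[MosaicAnnotation, ...]
    recency: tuple[RecencyCall, ...]
    markers: tuple[DiagnosticMarker, ...]
    trees: Mapping[str, str]

    def to_dict(self) -> dict:
        def ev_dict(ev: RecombinationEvent) -> dict:
            d = asdict(ev)
            d["p_values"] = dict(ev.p_values)
            return d

        return {
            "config": asdict(self.config),
            "candidates": list(self.candidates),
            "groups": dict(self.groups),
            "pi_candidates": dict(self.pi_candidates),
            "pi_candidates_hd_excluded": (
                dict(self.pi_candidates_hd_excluded)
                if self.pi_candidates_hd_excluded is not None
                else None
            ),
            "hd_regions_pi": [asdict(r) for r in self.hd_regions_pi],
            "hd_regions_pairwise": [asdict(r) for r in self.hd_regions_pairwise],
            "phi_global": dict(self.phi_global),
            "events": [ev_dict(e) for e in self.events],
            "annotations": [
                {
                    "genome_id": a.genome_id,
                    "backbone_id": a.backbone_id,
                    "events": [ev_dict(e) for e in a.events],
                    "notes": list(a.notes),
                }
                for a in self.annotations
            ],
            "recency": [
                {
                    "recombinant_id": r.event.recombinant_id,
                    "begin": r.event.begin,
                    "end": r.event.end,
                    "mismatches": r.mismatches,
                    "positions": list(r.positions),
                    "call": r.call,
                    "note": r.note,
                }
                for r in self.recency
            ],
            "markers": [
                {
                    "start": m.region.start,
                    "end": m.region.end,
                    "recombinant_id": m.recombinant_id,
                    "minor_parent_id": m.minor_parent_id,
                    "identity_fraction": m.identity_fraction,
                    "diagnostic_identical": m.diagnostic_identical,
                }
                for m in self.markers
            ],
            "trees": dict(self.trees),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        with open(out / "events.tsv", "w") as fh:
            fh.write(
                "event\trecombinant\tmajor_parent\tminor_parent\tbegin\tend\t"
                "span\tungapped_length\tmismatches\tp_combined\tp_corrected\n"
            )
            for k, ev in enumerate(self.events, start=1):
                fh.write(
                    f"{k}\t{ev.recombinant_id}\t{ev.major_parent_id}\t"
                    f"{ev.minor_parent_id}\t{ev.begin}\t{ev.end}\t{ev.span}\t"
                    f"{ev.ungapped_length}\t{ev.mismatches}\t"
                    f"{ev.p_values['combined']:.3e}\t{ev.p_values['corrected']:.3e}\n"
                )
        with open(out / "hd_regions.tsv", "w") as fh:
            fh.write("source\tstart\tend\tpeak_midpoint\tpeak_value\tbackground\n")
            for src, regs in (
                ("pi", self.hd_regions_pi),
                ("pairwise", self.hd_regions_pairwise),
            ):
                for r in regs:
                    fh.write(
                        f"{src}\t{r.start}\t{r.end}\t{r.peak_midpoint}\t"
                        f"{r.peak_value:.6f}\t{r.background:.6f}\n"
                    )
        for name, nwk in self.trees.items():
            (out / f"tree_{name}.nwk").write_text(nwk + "\n")


def run_pipeline(
    aln: MultipleAlignment,
    candidates: Sequence[str],
    groups: Mapping[str, str],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run every stage in order and assemble the report.

    Stages: candidate diversity profile -> HD-region detection (group
    profile and pairwise panel) -> global PHI -> event calling -> mosaic
    annotation -> recency calls -> diagnostic markers -> summary trees.
    Stage failures propagate with the stage named in the log.
    """
    candidates = list(candidates)
    for cid in candidates:
        if cid not in aln.ids:
            raise ConfigurationError(f"candidate {cid!r} not in alignment")
    participant_ids = [i for i in aln.ids if i in groups]
    log.info(
        "pipeline start: %d sequences, %d candidates, seed=%s",
        len(aln), len(candidates), config.seed,
    )

    cand_aln = aln.subset(candidates) if len(candidates) >= 2 else None

    log.info("stage: sliding-window diversity scan (window=%d step=%d)",
             config.window, config.step)
    if cand_aln is not None:
        profile = sliding_profile(
            cand_aln, "pi", config.window, config.step, config.deletion_policy
        )
        hd_pi = detect_hd_regions(
            profile, config.fold_threshold, config.min_windows, config.absolute_floor
        )
        pi_full = nucleotide_diversity(
            cand_aln, config.deletion_policy, config.n_bootstrap
        )
    else:
        profile, hd_pi, pi_full = None, [], None

    # the pairwise panel keeps its own run-length rule (window//step + 1):
    # config.min_windows governs the group-profile scan only
    hd_pair = hd_regions_from_pairs(
        aln, candidates, config.window, config.step,
        config.fold_threshold, None, config.absolute_floor,
    ) if len(candidates) >= 2 else []

    hd_for_deletion = hd_pair or hd_pi
    pi_deleted = None
    if cand_aln is not None and hd_for_deletion:
        reduced = delete_regions(
            cand_aln, [RegionSpec(r.start, r.end, "HD") for r in hd_for_deletion]
        )
        pi_deleted = nucleotide_diversity(
            reduced, config.deletion_policy, config.n_bootstrap
        )

    log.info("stage: global PHI test (%d permutations)", config.phi_permutations)
    phi = phi_test(
        aln.subset(participant_ids),
        w=config.phi_w,
        n_permutations=config.phi_permutations,
        seed=config.seed,
    )

    log.info("stage: event calling")
    events = call_events(aln, candidates, groups, config.recomb())
    log.info("events detected: %d", len(events))

    log.info("stage: mosaic annotation")
    annotations = []
    for cand in candidates:
        cand_events = [e for e in events if e.recombinant_id == cand]
        backbone = (
            cand_events[0].major_parent_id
            if cand_events
            else next(
                (i for i in participant_ids if groups[i] == groups[cand] and i != cand),
                cand,
            )
        )
        annotations.append(annotate_mosaic(cand_events, cand, backbone))

    kept_events = tuple(e for a in annotations for e in a.events)
    recency = tuple(count_fragment_mismatches(aln, e) for e in kept_events)
    markers = tuple(extract_markers(annotations, aln)) if annotations else ()

    log.info("stage: summary trees")
    trees: dict[str, str] = {}
    if len(participant_ids) >= 3:
        dm = distance_matrix(
            aln.subset(participant_ids), config.deletion_policy, n_bootstrap=0
        )
        trees["full"] = nj_tree(dm)
        if hd_for_deletion:
            reduced_all = delete_regions(
                aln.subset(participant_ids),
                [RegionSpec(r.start, r.end, "HD") for r in hd_for_deletion],
            )
            trees["hd_excluded"] = nj_tree(
                distance_matrix(reduced_all, config.deletion_policy, n_bootstrap=0)
            )
            for k, reg in enumerate(hd_for_deletion, start=1):
                sub = aln.subset(participant_ids)
                from .alignio import extract_region

                region_aln = extract_region(sub, RegionSpec(reg.start, reg.end))
                try:
                    trees[f"hd_region_{k}"] = nj_tree(
                        distance_matrix(region_aln, config.deletion_policy, n_bootstrap=0)
                    )
                except AlignmentError:
                    pass

    def div_dict(d) -> Mapping[str, float] | None:
        if d is None:
            return None
        return {"pi": d.pi, "se": d.se, "n_sequences": d.n_sequences}

    report = PipelineReport(
        config=config,
        candidates=tuple(candidates),
        groups={k: groups[k] for k in participant_ids},
        pi_candidates=div_dict(pi_full) or {},
        pi_candidates_hd_excluded=div_dict(pi_deleted),
        hd_regions_pi=tuple(hd_pi),
        hd_regions_pairwise=tuple(hd_pair),
        phi_global={
            "statistic": None if not phi.computable else phi.statistic,
            "p_value": None if not phi.computable else phi.p_value,
            "n_informative": phi.n_informative,
            "n_permutations": phi.n_permutations,
            "computable": phi.computable,
        },
        events=tuple(events),
        annotations=tuple(annotations),
        recency=recency,
        markers=markers,
        trees=trees,
    )
    if out_dir is not None:
        report.write(out_dir)
        if profile is not None:
            profile.write(Path(out_dir) / "profile_pi.tsv")
        log.info("report written to %s", out_dir)
    return report
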