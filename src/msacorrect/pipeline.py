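"""End-to-end correction driver: construction -> correction -> merge.

Construction builds the minhash tables over all reads.  Correction treats
every read in turn as the anchor: retrieve candidates, align them, filter
(mate-aware in paired mode), build and refine the MSA, then correct the
anchor — and, from high-quality MSAs, nearby candidates.  Merge reconciles
the per-read records into the final output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence


from . import classic, forest as forest_mod
from .align import Candidate, FilterParams, align_shd, filter_paired, filter_single
from .classic import CorrectionRecord, QualityThresholds
from .io_encodings import EncodedRead
from .merge import MergeDecision, merge_corrections
from .minhash import build_index, make_seeds, query_candidates
from .msa import RefinementParams, build_msa, refine_msa

__all__ = ["PipelineConfig", "CorrectionResult", "run_correction"]


@dataclass
class PipelineConfig:
    coverage: float  # estimated dataset fold-coverage (required, no auto-estimate)
    kmer_length: int = 20
    num_tables: int = 48
    paired: bool = False
    mode: str = "classic"  # classic | forest
    min_overlap_ratio: float = 0.3
    max_mismatch_ratio: float = 0.2
    t_paired: float = 0.06
    refinement_factor: float = 0.3
    max_refinement_iters: int = 5
    candidate_margin: int = 15
    candidate_correction: bool = True
    use_quality: bool = True
    anchor_threshold: float = 0.7
    candidate_threshold: float = 0.7
    hq_thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    max_candidates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.mode not in ("classic", "forest"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def filter_params(self) -> FilterParams:
        return FilterParams(
            max_mismatch_ratio=self.max_mismatch_ratio,
            t_paired=self.t_paired,
            min_overlap_ratio=self.min_overlap_ratio,
        )

    def refinement_params(self) -> RefinementParams:
        return RefinementParams(
            estimated_coverage=self.coverage,
            frequency_factor=self.refinement_factor,
            max_iterations=self.max_refinement_iters,
        )


@dataclass
class CorrectionResult:
    corrected_reads: list[EncodedRead]
    records: list[CorrectionRecord]
    audit: list[MergeDecision]
    report: dict
    harvest: Optional[dict] = None


def _retrieve_and_align(reads, index, anchor, config) -> list[Candidate]:
    ids = query_candidates(index, anchor, config.max_candidates)
    out = []
    for rid in sorted(ids):
        aln = align_shd(anchor, reads[rid], config.min_overlap_ratio)
        if aln.valid:
            out.append(Candidate(reads[rid], aln))
    return out


def run_correction(
    reads: Sequence[EncodedRead],
    config: PipelineConfig,
    anchor_model=None,
    candidate_model=None,
    harvest_with: Optional[Sequence[EncodedRead]] = None,
) -> CorrectionResult:
    """Run all three phases over ``reads`` and return the corrected dataset.

    In forest mode both models must be supplied.  With ``harvest_with`` (the
    error-free twin of ``reads``) the pipeline additionally emits labelled
    training feature vectors from exactly the MSAs inference would build.
    """
    if config.mode == "forest" and (anchor_model is None or candidate_model is None):
        raise ValueError("forest mode requires anchor and candidate models")
    if harvest_with is not None and len(harvest_with) != len(reads):
        raise ValueError("error-free twin must match the read count")
    if config.paired and len(reads) % 2:
        raise ValueError("paired mode requires an even read count")

    seeds = make_seeds(config.num_tables, config.seed)
    index = build_index(reads, k=config.kmer_length, seeds=seeds)
    fparams = config.filter_params()
    rparams = config.refinement_params()

    records: list[CorrectionRecord] = []
    harvest = (
        {"anchor_X": [], "anchor_y": [], "candidate_X": [], "candidate_y": []}
        if harvest_with is not None
        else None
    )
    stats = {
        "anchors_processed": 0,
        "anchors_skipped_unindexable": 0,
        "anchors_without_candidates": 0,
        "candidates_retrieved": 0,
        "candidates_after_filter": 0,
        "candidates_removed_by_refinement": 0,
        "high_quality_msas": 0,
        "low_quality_msas": 0,
        "anchor_records": 0,
        "candidate_records": 0,
    }

    def _process(anchor: EncodedRead, filtered: list[Candidate]) -> None:
        stats["anchors_processed"] += 1
        if not filtered:
            stats["anchors_without_candidates"] += 1
        msa = build_msa(anchor, filtered, use_quality=config.use_quality)
        msa, removed = refine_msa(msa, rparams)
        stats["candidates_removed_by_refinement"] += sum(len(s) for s in removed)
        quality = classic.classify_msa(msa, config.hq_thresholds)
        stats["high_quality_msas" if quality.is_high_quality else "low_quality_msas"] += 1
        alignments = {c.read.read_id: c.alignment for c in filtered}

        if config.mode == "forest":
            rec = forest_mod.correct_anchor_forest(
                anchor, msa, quality, anchor_model, config.anchor_threshold,
                config.coverage,
            )
        else:
            rec = classic.correct_anchor_classic(anchor, msa, quality)
        records.append(rec)
        stats["anchor_records"] += 1

        if config.candidate_correction and quality.is_high_quality:
            if config.mode == "forest":
                cand_recs = forest_mod.correct_candidates_forest(
                    msa, quality, config.candidate_margin, candidate_model,
                    config.candidate_threshold, config.coverage, alignments,
                )
            else:
                cand_recs = classic.correct_candidates(
                    msa, quality, config.candidate_margin
                )
            records.extend(cand_recs)
            stats["candidate_records"] += len(cand_recs)

        if harvest is not None:
            _harvest_examples(msa, quality, alignments, harvest)

    def _harvest_examples(msa, quality, alignments, harvest) -> None:
        ctx = forest_mod.MsaContext.from_msa(msa)
        a0 = msa.column_of(0)
        if not quality.is_high_quality:
            member = msa.anchor
            truth = harvest_with[member.read.read_id].codes
            for j in range(msa.anchor_length):
                if member.row_codes[j] >= 4 or member.row_codes[j] == ctx.cons[a0 + j]:
                    continue
                fv = forest_mod.extract_features(
                    msa, member, j, config.coverage, ctx
                )
                harvest["anchor_X"].append(fv)
                harvest["anchor_y"].append(int(ctx.cons[a0 + j] == truth[j]))
        elif config.candidate_correction:
            from .io_encodings import reverse_complement

            for m in msa.members:
                if m.is_anchor:
                    continue
                begin, end = m.shift, m.shift + len(m.row_codes)
                if begin < -config.candidate_margin or end > (
                    msa.anchor_length + config.candidate_margin
                ):
                    continue
                truth = harvest_with[m.read.read_id].codes
                if m.orientation == "rc":
                    truth = reverse_complement(truth)
                aln = alignments[m.read.read_id]
                for j in range(len(m.row_codes)):
                    c = msa.column_of(m.shift + j)
                    if m.row_codes[j] >= 4 or m.row_codes[j] == ctx.cons[c]:
                        continue
                    fv = forest_mod.extract_features(
                        msa, m, j, config.coverage, ctx, aln
                    )
                    harvest["candidate_X"].append(fv)
                    harvest["candidate_y"].append(int(ctx.cons[c] == truth[j]))

    n = len(reads)
    if config.paired:
        for i in range(0, n, 2):
            a0, a1 = reads[i], reads[i + 1]
            c0 = _retrieve_and_align(reads, index, a0, config)
            c1 = _retrieve_and_align(reads, index, a1, config)
            stats["candidates_retrieved"] += len(c0) + len(c1)
            f0, f1 = filter_paired(c0, c1, fparams)
            stats["candidates_after_filter"] += len(f0) + len(f1)
            _process(a0, f0)
            _process(a1, f1)
    else:
        for i in range(n):
            cands = _retrieve_and_align(reads, index, reads[i], config)
            stats["candidates_retrieved"] += len(cands)
            filtered = filter_single(cands, fparams)
            stats["candidates_after_filter"] += len(filtered)
            _process(reads[i], filtered)

    stats["anchors_skipped_unindexable"] = len(index.unindexable)
    corrected, audit = merge_corrections(records, list(reads))
    decisions = {}
    for d in audit:
        decisions[d.decision] = decisions.get(d.decision, 0) + 1
    report = {
        "config": asdict(config),
        "n_reads": n,
        "merge_decisions": decisions,
        **stats,
    }
    return CorrectionResult(corrected, records, audit, report, harvest)
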