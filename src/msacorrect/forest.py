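"""Random-forest per-base correction: features, portable models, training.

For low-quality MSAs the hand-crafted correction rule is replaced by an
ensemble classifier: every anchor position whose base disagrees with the
column consensus is described by a feature vector (local column statistics
plus global MSA aggregates) and changed to the consensus only when the
forest's mean positive-class probability surpasses a user-chosen threshold.
A second forest with additional alignment features vets candidate
corrections.  Models are trained on simulated reads where an error-free twin
provides per-base labels, and are serialized to a portable JSON container
(feature schema + flattened tree arrays) rather than pickled code.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import AlignmentResult
from .classic import CorrectionRecord, MsaQuality, _edits
from .io_encodings import EncodedRead, reverse_complement
from .msa import Msa, MsaMember

__all__ = [
    "ANCHOR_FEATURES",
    "CANDIDATE_FEATURES",
    "ForestModel",
    "TrainingDataset",
    "extract_features",
    "predict_correction",
    "correct_anchor_forest",
    "correct_candidates_forest",
    "train_forests",
]

SCHEMA_VERSION = 1
_BASES = "ACGT"

ANCHOR_FEATURES = (
    "orig_base_count_frac",
    "cons_base_count_frac",
    "orig_base_weight_frac",
    "cons_base_weight_frac",
    "orig_base_quality",
    "cons_mean_quality",
    "column_support",
    "column_coverage",
    "relative_position",
    "read_mean_support",
    "msa_min_coverage",
    "msa_avg_coverage",
    "msa_max_coverage",
    "msa_min_support",
    "msa_avg_support",
    "coverage_ratio_to_estimate",
)

CANDIDATE_FEATURES = ANCHOR_FEATURES + (
    "overlap_frac",
    "mismatches",
    "mismatch_ratio",
    "shift_frac",
)


@dataclass
class MsaContext:
    """Precomputed per-MSA quantities shared by all positions scored in it."""

    cons: np.ndarray
    support: np.ndarray
    coverage: np.ndarray
    min_cov: float
    avg_cov: float
    max_cov: float
    min_sup: float
    avg_sup: float

    @classmethod
    def from_msa(cls, msa: Msa) -> "MsaContext":
        cons = msa.consensus()
        support = msa.support(cons)
        coverage = msa.coverage().astype(float)
        a0 = msa.column_of(0)
        sl = slice(a0, a0 + msa.anchor_length)
        return cls(
            cons,
            support,
            coverage,
            float(coverage[sl].min()),
            float(coverage[sl].mean()),
            float(coverage[sl].max()),
            float(support[sl].min()),
            float(support[sl].mean()),
        )


def extract_features(
    msa: Msa,
    member: MsaMember,
    position: int,
    estimated_coverage: float,
    ctx: Optional[MsaContext] = None,
    alignment: Optional[AlignmentResult] = None,
) -> np.ndarray:
    """Feature vector for one row position (anchor-oriented index).

    ``position`` indexes ``member.row_codes``; with ``alignment`` given the
    four candidate-specific features are appended.  Raises on positions the
    member does not cover with a called base.
    """
    if not 0 <= position < len(member.row_codes):
        raise ValueError("position not covered by the read")
    orig = int(member.row_codes[position])
    if orig >= 4:
        raise ValueError("position is an N in the read")
    if ctx is None:
        ctx = MsaContext.from_msa(msa)
    c = msa.column_of(member.shift + position)
    cons = int(ctx.cons[c])
    cnt = msa.counts[:, c].astype(float)
    wgt = msa.weights[:, c]
    tot_c = cnt.sum() or 1.0
    tot_w = wgt.sum() or 1.0
    qual = member.read.quality.astype(float)
    if member.orientation == "rc":
        qual = qual[::-1]
    orig_q = 1.0 - 10.0 ** (-qual[position] / 10.0)
    cons_mean_q = wgt[cons] / cnt[cons] if cnt[cons] else 0.0
    span = slice(
        msa.column_of(member.shift),
        msa.column_of(member.shift + len(member.row_codes)),
    )
    ec = float(estimated_coverage)
    feats = [
        cnt[orig] / tot_c,
        cnt[cons] / tot_c,
        wgt[orig] / tot_w,
        wgt[cons] / tot_w,
        orig_q,
        cons_mean_q,
        ctx.support[c],
        ctx.coverage[c],
        position / len(member.row_codes),
        float(ctx.support[span].mean()),
        ctx.min_cov / ec,
        ctx.avg_cov / ec,
        ctx.max_cov / ec,
        ctx.min_sup,
        ctx.avg_sup,
        ctx.coverage[c] / ec,
    ]
    if alignment is not None:
        feats += [
            alignment.overlap / msa.anchor_length,
            float(alignment.mismatches),
            alignment.mismatch_ratio,
            abs(alignment.shift) / msa.anchor_length,
        ]
    return np.asarray(feats)


# ---------------------------------------------------------------------------
# Portable forest model


class ModelError(ValueError):
    pass


@dataclass
class ForestModel:
    """Ensemble of decision trees stored as flat arrays.

    ``trees`` holds per-tree dicts of numpy arrays (``children_left``,
    ``children_right``, ``feature``, ``threshold``, ``leaf_prob``); traversal
    reproduces scikit-learn's ``predict_proba`` (mean leaf class fraction
    over trees) without shipping pickled estimator code.
    """

    role: str  # "anchor" | "candidate"
    feature_names: tuple[str, ...]
    trees: list[dict]
    metadata: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @classmethod
    def from_sklearn(cls, clf, role: str, feature_names, metadata=None) -> "ForestModel":
        classes = list(clf.classes_)
        trees = []
        for est in clf.estimators_:
            t = est.tree_
            value = t.value[:, 0, :]  # (n_nodes, n_classes) class fractions
            if len(classes) == 1:
                leaf_prob = np.full(t.node_count, 1.0 if classes[0] else 0.0)
            else:
                pos = classes.index(1) if 1 in classes else classes.index(True)
                leaf_prob = value[:, pos] / value.sum(axis=1)
            trees.append(
                {
                    "children_left": t.children_left.copy(),
                    "children_right": t.children_right.copy(),
                    "feature": t.feature.copy(),
                    "threshold": t.threshold.copy(),
                    "leaf_prob": leaf_prob,
                }
            )
        return cls(role, tuple(feature_names), trees, dict(metadata or {}))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean positive-class probability over trees, one value per row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ModelError(
                f"feature vector has {X.shape[1]} entries; model "
                f"({self.role}) expects {len(self.feature_names)}"
            )
        n = X.shape[0]
        acc = np.zeros(n)
        for t in self.trees:
            node = np.zeros(n, dtype=np.int64)
            left, right = t["children_left"], t["children_right"]
            feat, thr = t["feature"], t["threshold"]
            while True:
                active = left[node] != -1
                if not active.any():
                    break
                idx = node[active]
                go_left = X[active, feat[idx]] <= thr[idx]
                node[active] = np.where(go_left, left[idx], right[idx])
            acc += t["leaf_prob"][node]
        return acc / self.n_trees

    def save(self, path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "role": self.role,
            "feature_names": list(self.feature_names),
            "metadata": self.metadata,
            "trees": [
                {k: np.asarray(v).tolist() for k, v in t.items()} for t in self.trees
            ],
        }
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as out:
            json.dump(payload, out)

    @classmethod
    def load(cls, path) -> "ForestModel":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            payload = json.load(handle)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ModelError(f"{path}: unsupported model schema")
        trees = []
        for t in payload["trees"]:
            trees.append(
                {
                    "children_left": np.asarray(t["children_left"], dtype=np.int64),
                    "children_right": np.asarray(t["children_right"], dtype=np.int64),
                    "feature": np.asarray(t["feature"], dtype=np.int64),
                    "threshold": np.asarray(t["threshold"], dtype=float),
                    "leaf_prob": np.asarray(t["leaf_prob"], dtype=float),
                }
            )
        return cls(
            payload["role"], tuple(payload["feature_names"]), trees, payload["metadata"]
        )


def predict_correction(model: ForestModel, fv: np.ndarray, threshold: float) -> bool:
    """True when the mean positive probability strictly surpasses the cutoff."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return bool(model.predict_proba(fv)[0] > threshold)


# ---------------------------------------------------------------------------
# Correction with forests


def correct_anchor_forest(
    anchor: EncodedRead,
    msa: Msa,
    quality: MsaQuality,
    model: ForestModel,
    threshold: float,
    estimated_coverage: float,
) -> CorrectionRecord:
    """Anchor correction: consensus outright for high-quality MSAs, else
    per-position forest decisions on the consensus-discordant positions."""
    original = anchor.sequence
    a0 = msa.column_of(0)
    ctx = MsaContext.from_msa(msa)
    member = msa.anchor
    out = list(original)
    if quality.is_high_quality:
        for j in range(anchor.length):
            out[j] = _BASES[ctx.cons[a0 + j]]
    else:
        positions = [
            j
            for j in range(anchor.length)
            if member.row_codes[j] < 4 and member.row_codes[j] != ctx.cons[a0 + j]
        ]
        if positions:
            X = np.stack(
                [
                    extract_features(msa, member, j, estimated_coverage, ctx)
                    for j in positions
                ]
            )
            probs = model.predict_proba(X)
            for j, p in zip(positions, probs):
                if p > threshold:
                    out[j] = _BASES[ctx.cons[a0 + j]]
    corrected = "".join(out)
    return CorrectionRecord(
        anchor.read_id, corrected, "anchor", _edits(original, corrected)
    )


def correct_candidates_forest(
    msa: Msa,
    quality: MsaQuality,
    margin: int,
    model: ForestModel,
    threshold: float,
    estimated_coverage: float,
    alignments: dict[int, AlignmentResult],
) -> list[CorrectionRecord]:
    """Candidate corrections with per-position vetting by the candidate forest.

    Same containment gate as the rule-based path (candidate fully inside
    ``[b - margin, e + margin)`` of a high-quality MSA); each position where
    the candidate disagrees with the consensus is changed only if the forest
    approves it.
    """
    if not quality.is_high_quality:
        raise ValueError("candidate corrections require a high-quality MSA")
    ctx = MsaContext.from_msa(msa)
    eligible = []
    feats, owners = [], []
    for m in msa.members:
        if m.is_anchor:
            continue
        begin, end = m.shift, m.shift + len(m.row_codes)
        if begin < -margin or end > msa.anchor_length + margin:
            continue
        aln = alignments[m.read.read_id]
        row = m.row_codes
        changed = row.copy()
        # N positions always take the consensus: the read carries no evidence
        for j in range(len(row)):
            if row[j] >= 4:
                changed[j] = ctx.cons[msa.column_of(m.shift + j)]
        positions = [
            j
            for j in range(len(row))
            if row[j] < 4 and row[j] != ctx.cons[msa.column_of(m.shift + j)]
        ]
        eligible.append((m, changed))
        for j in positions:
            feats.append(extract_features(msa, m, j, estimated_coverage, ctx, aln))
            owners.append((len(eligible) - 1, j))
    if feats:
        # one batched ensemble call per MSA: per-record calls dominate runtime
        probs = model.predict_proba(np.stack(feats))
        for (mi, j), p in zip(owners, probs):
            if p > threshold:
                m, changed = eligible[mi]
                changed[j] = ctx.cons[msa.column_of(m.shift + j)]
    records = []
    for m, changed in eligible:
        if m.orientation == "rc":
            changed = reverse_complement(changed)
        corrected = "".join(_BASES[b] for b in changed)
        original = m.read.sequence
        records.append(
            CorrectionRecord(
                m.read.read_id, corrected, "candidate", _edits(original, corrected)
            )
        )
    return records


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainingDataset:
    """A simulated dataset with ground truth for label derivation."""

    reads: Sequence[EncodedRead]
    error_free: Sequence[EncodedRead]
    genome_tag: str


class TrainingDataError(ValueError):
    pass


def train_forests(
    datasets: Sequence[TrainingDataset],
    pipeline_config,
    n_trees: int = 128,
    seed: int = 0,
    exclude_tags: Sequence[str] = (),
    max_examples_per_role: int = 50_000,
) -> tuple[ForestModel, ForestModel]:
    """Fit anchor and candidate forests from harvested pipeline features.

    The correction pipeline runs in feature-harvest mode on each training
    dataset so that training MSAs are identical to inference MSAs.  An
    example's label is positive exactly when applying the consensus at that
    position would restore the error-free base.  Genomes named in
    ``exclude_tags`` are held out (leave-one-genome-out protocol).
    """
    from sklearn.ensemble import RandomForestClassifier

    from .pipeline import run_correction

    used_tags = []
    aX, ay, cX, cy = [], [], [], []
    for ds in datasets:
        if ds.genome_tag in exclude_tags:
            continue
        used_tags.append(ds.genome_tag)
        result = run_correction(
            ds.reads, pipeline_config, harvest_with=ds.error_free
        )
        h = result.harvest
        aX.extend(h["anchor_X"])
        ay.extend(h["anchor_y"])
        cX.extend(h["candidate_X"])
        cy.extend(h["candidate_y"])
    if not used_tags:
        raise TrainingDataError("all training datasets were excluded")
    if not aX:
        raise TrainingDataError("no low-quality MSAs harvested; nothing to train on")
    if not cX:
        raise TrainingDataError("no candidate positions harvested")

    def _fit(X, y, role):
        X, y = np.stack(X), np.asarray(y, dtype=int)
        if len(y) > max_examples_per_role:
            rng = np.random.default_rng(seed)
            pick = rng.choice(len(y), size=max_examples_per_role, replace=False)
            X, y = X[pick], y[pick]
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        clf.fit(X, y)
        names = ANCHOR_FEATURES if role == "anchor" else CANDIDATE_FEATURES
        meta = {
            "training_genomes": used_tags,
            "excluded_genomes": list(exclude_tags),
            "seed": seed,
            "n_examples": len(y),
            "positive_examples": int(np.sum(y)),
        }
        return ForestModel.from_sklearn(clf, role, names, meta)

    return _fit(aX, ay, "anchor"), _fit(cX, cy, "candidate")
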