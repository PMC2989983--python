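"""End-to-end training/prediction pipelines, cross-validation, and metrics.

Cross-validation is performed at the sequence level: whole proteins are
assigned to folds so that no protein contributes fragments to both a training
and a test set.  Fold confusion counts are pooled (micro-averaged) into the
headline metrics.  For transmembrane proteins an optional topology filter
vetoes positive predictions that fall inside a TM segment, since such sites
cannot be reached by the glycosyltransferase machinery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import rbfn
from .features import encode_blosum62, encode_saaps
from .homology import dedup_fragments
from .rbfn import FeatureSchema, RBFNModel
from .sequence_io import (
    NEGATIVE,
    POSITIVE,
    ProteinRecord,
    SiteAnnotation,
    SiteFragment,
    TopologySegment,
    candidate_sites,
    extract_window,
    label_at,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts plus the derived performance statistics.

    Conventions: a zero denominator yields 0 for the rate in question, and an
    all-zero MCC denominator yields MCC = 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    pr: float
    sn: float
    sp: float
    acc: float
    bacc: float
    mcc: float

    def rounded(self) -> dict[str, float]:
        """Percentages at 1 decimal and MCC at 2 decimals (report style)."""
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "pr_pct": round(100 * self.pr, 1),
            "sn_pct": round(100 * self.sn, 1),
            "sp_pct": round(100 * self.sp, 1),
            "acc_pct": round(100 * self.acc, 1),
            "bacc_pct": round(100 * self.bacc, 1),
            "mcc": round(self.mcc, 2),
        }


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Derive Pr, Sn, Sp, Acc, BAcc and MCC from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    pr = ratio(tp, tp + fp)
    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    acc = ratio(tp + tn, tp + fp + tn + fn)
    bacc = (sn + sp) / 2.0
    den = (
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = 0.0 if den == 0 else (tp * tn - fn * fp) / math.sqrt(den)
    return ConfusionMetrics(tp, fp, tn, fn, pr, sn, sp, acc, bacc, mcc)


def split_folds(
    protein_ids: Sequence[str], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Uniformly random sequence-level fold assignment; sizes differ by <= 1."""
    ids = sorted(set(protein_ids))
    if len(ids) < k:
        raise ValueError(f"need at least {k} proteins for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            assignment[ids[idx]] = fold
    return assignment


def encode_fragments(
    fragments: Sequence[SiteFragment], saap_list: Sequence = ()
) -> np.ndarray:
    base = np.array([encode_blosum62(f) for f in fragments])
    if not saap_list:
        return base
    bits = np.array([encode_saaps(f, saap_list) for f in fragments])
    return np.hstack([base, bits])


@dataclass
class CVResult:
    fold_metrics: list[ConfusionMetrics]
    pooled: ConfusionMetrics
    fold_sizes: list[int]
    warnings: list[str] = field(default_factory=list)


def run_cv(
    fragments: Sequence[SiteFragment],
    protein_sequences: Mapping[str, str],
    saap_list: Sequence = (),
    *,
    folds: int = 5,
    seed: int = 0,
    sigma: float = 5.0,
    ridge_lambda: float = 0.0,
    threshold: float = 0.0,
    homology: str = "per-fold",
    identity_threshold: float = 30.0,
) -> CVResult:
    """Sequence-level k-fold cross-validation of the RBFN classifier.

    ``homology`` controls redundancy reduction: "per-fold" (default) reduces
    each training fold against its own proteins, "global" reduces the whole
    fragment set once before splitting, "none" skips it.  Test fragments are
    never removed, so pooled counts conserve the input totals.
    """
    if homology not in ("per-fold", "global", "none"):
        raise ValueError("homology must be 'per-fold', 'global' or 'none'")
    if homology == "global":
        fragments, _ = dedup_fragments(fragments, protein_sequences, identity_threshold)

    assignment = split_folds([f.protein_id for f in fragments], k=folds, seed=seed)
    encoded = encode_fragments(fragments, saap_list)
    labels = np.array([f.label == POSITIVE for f in fragments])

    warnings: list[str] = []
    fold_metrics: list[ConfusionMetrics] = []
    fold_sizes: list[int] = []
    tp = fp = tn = fn = 0
    for fold in range(folds):
        test_mask = np.array([assignment[f.protein_id] == fold for f in fragments])
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        if not labels[test_idx].any():
            msg = f"fold {fold}: no positive fragments in the test split"
            warnings.append(msg)
            logger.warning(msg)
        if homology == "per-fold":
            train_frags = [fragments[i] for i in train_idx]
            kept, _ = dedup_fragments(train_frags, protein_sequences, identity_threshold)
            kept_keys = {(f.protein_id, f.position, f.label) for f in kept}
            train_idx = np.array(
                [
                    i
                    for i in train_idx
                    if (
                        fragments[i].protein_id,
                        fragments[i].position,
                        fragments[i].label,
                    )
                    in kept_keys
                ]
            )
        if labels[train_idx].all() or not labels[train_idx].any():
            msg = f"fold {fold}: training split holds one class only; skipped"
            warnings.append(msg)
            logger.warning(msg)
            continue
        model = rbfn.fit(
            encoded[train_idx],
            labels[train_idx],
            sigma=sigma,
            ridge_lambda=ridge_lambda,
        )
        scores = rbfn.predict_scores_batch(model, encoded[test_idx])
        calls = (scores[:, 1] - scores[:, 0]) > threshold
        truth = labels[test_idx]
        f_tp = int(np.sum(calls & truth))
        f_fp = int(np.sum(calls & ~truth))
        f_tn = int(np.sum(~calls & ~truth))
        f_fn = int(np.sum(~calls & truth))
        fold_metrics.append(compute_metrics(f_tp, f_fp, f_tn, f_fn))
        fold_sizes.append(len(test_idx))
        tp, fp, tn, fn = tp + f_tp, fp + f_fp, tn + f_tn, fn + f_fn
        logger.info(
            "fold %d: tp=%d fp=%d tn=%d fn=%d", fold, f_tp, f_fp, f_tn, f_fn
        )
    return CVResult(fold_metrics, compute_metrics(tp, fp, tn, fn), fold_sizes, warnings)


def make_cv_trainer(
    protein_sequences: Mapping[str, str],
    *,
    folds: int = 5,
    seed: int = 0,
    sigma: float = 5.0,
    ridge_lambda: float = 0.0,
    homology: str = "per-fold",
):
    """A ``model_trainer`` callback for forward selection: pooled CV BAcc."""

    def trainer(fragments: Sequence[SiteFragment], saap_prefix: Sequence) -> float:
        result = run_cv(
            fragments,
            protein_sequences,
            saap_prefix,
            folds=folds,
            seed=seed,
            sigma=sigma,
            ridge_lambda=ridge_lambda,
            homology=homology,
        )
        return result.pooled.bacc

    return trainer


@dataclass(frozen=True)
class SitePrediction:
    """One scored candidate site, optionally carrying its ground truth."""

    protein_id: str
    position: int
    residue: str
    protein_class: str  # "TM" or "nonTM"
    score_pos: float
    score_neg: float
    decision: str  # POSITIVE or NEGATIVE
    topology_label: str = "Unknown"
    matched_saaps: tuple[str, ...] = ()
    true_label: str | None = None


def topology_filter(
    predictions: Sequence[SitePrediction],
    topology: Mapping[str, Sequence[TopologySegment]],
) -> list[SitePrediction]:
    """Veto positive predictions lying inside transmembrane segments.

    Predictions outside TM segments — and all negative predictions — pass
    through unchanged; proteins without topology are untouched.
    """
    out: list[SitePrediction] = []
    for pred in predictions:
        segments = topology.get(pred.protein_id, [])
        if pred.decision == POSITIVE and label_at(segments, pred.position) == "TM":
            out.append(replace(pred, decision=NEGATIVE, topology_label="TM"))
        else:
            out.append(pred)
    return out


def tally_topology(
    sites: Iterable[SiteAnnotation],
    topology: Mapping[str, Sequence[TopologySegment]],
) -> dict[str, int]:
    """Count sites per topology label (uncovered positions count as Unknown)."""
    counts = {label: 0 for label in ("L", "N", "E", "C", "TM", "S", "Unknown")}
    for site in sites:
        label = label_at(topology.get(site.protein_id, []), site.position)
        counts[label] += 1
    return counts


def confusion_from_predictions(
    predictions: Sequence[SitePrediction],
) -> ConfusionMetrics:
    """Confusion metrics from predictions that carry their true labels."""
    tp = fp = tn = fn = 0
    for p in predictions:
        if p.true_label is None:
            raise ValueError("prediction lacks a ground-truth label")
        called = p.decision == POSITIVE
        actual = p.true_label == POSITIVE
        tp += called and actual
        fp += called and not actual
        tn += not called and not actual
        fn += not called and actual
    return compute_metrics(tp, fp, tn, fn)


def predict_protein(
    record: ProteinRecord,
    models: Mapping[tuple[str, str], RBFNModel],
    *,
    use_topology: bool = False,
    threshold: float = 0.0,
    positive_positions: Iterable[int] = (),
) -> list[SitePrediction]:
    """Score every S/T site of a protein with its (residue, class) model.

    ``models`` maps (center residue, protein class) — e.g. ("S", "TM") — to a
    trained RBFN whose schema fixes the window size and SAAP list.  With
    ``use_topology`` set and a TM protein, positive calls inside TM segments
    are vetoed.
    """
    cls = "TM" if record.is_tm else "nonTM"
    positives = set(positive_positions)
    predictions: list[SitePrediction] = []
    for site in candidate_sites(record, positives):
        key = (site.residue, cls)
        if key not in models:
            raise KeyError(f"no model for stratum {site.residue}/{cls}")
        model = models[key]
        schema = model.feature_schema
        if schema is None:
            raise ValueError("model lacks a feature schema")
        frag = extract_window(record, site.position, schema.n)
        x = encode_blosum62(frag)
        if schema.saap_list:
            bits = encode_saaps(frag, schema.saap_list)
            matched = tuple(
                schema.saap_list[j].describe()
                for j in np.flatnonzero(bits)
            )
            x = np.concatenate([x, bits])
        else:
            matched = ()
        s_pos, s_neg = rbfn.predict_scores(model, x)
        decision = POSITIVE if s_pos - s_neg > threshold else NEGATIVE
        predictions.append(
            SitePrediction(
                protein_id=record.id,
                position=site.position,
                residue=site.residue,
                protein_class=cls,
                score_pos=s_pos,
                score_neg=s_neg,
                decision=decision,
                topology_label=label_at(record.topology, site.position),
                matched_saaps=matched,
                true_label=site.label if positives else None,
            )
        )
    if use_topology and record.is_tm:
        predictions = topology_filter(predictions, {record.id: record.topology})
    return predictions


def write_predictions(predictions: Sequence[SitePrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#protein_id\tposition\tresidue\tclass\tscore_pos\tscore_neg"
            "\tdecision\ttopology_label\tmatched_saaps\n"
        )
        for p in predictions:
            fh.write(
                f"{p.protein_id}\t{p.position}\t{p.residue}\t{p.protein_class}"
                f"\t{p.score_pos:.6g}\t{p.score_neg:.6g}\t{p.decision}"
                f"\t{p.topology_label}\t{';'.join(p.matched_saaps)}\n"
            )


def metrics_report(columns: Mapping[str, ConfusionMetrics]) -> str:
    """Human-readable metrics table (one column per labeled configuration)."""
    rows = [
        ("True Positive", "tp"),
        ("False Positive", "fp"),
        ("True Negative", "tn"),
        ("False Negative", "fn"),
        ("Precision", "pr_pct"),
        ("Sensitivity", "sn_pct"),
        ("Specificity", "sp_pct"),
        ("Accuracy", "acc_pct"),
        ("Balanced Accuracy", "bacc_pct"),
        ("MCC", "mcc"),
    ]
    names = list(columns)
    width = max(18, *(len(n) for n in names)) + 2
    lines = ["".ljust(20) + "".join(n.ljust(width) for n in names)]
    for label, key in rows:
        cells = []
        for name in names:
            value = columns[name].rounded()[key]
            if key.endswith("_pct"):
                cells.append(f"{value:.1f}%")
            elif key == "mcc":
                cells.append(f"{value:.2f}")
            else:
                cells.append(str(value))
        lines.append(label.ljust(20) + "".join(c.ljust(width) for c in cells))
    return "\n".join(lines)
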