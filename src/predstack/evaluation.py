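"""Evaluation statistics for predictor panels.

Implements the correctness/accuracy/confidence definitions, pooled
per-class accuracy, per-protein accuracy correlation, the five-way
agreement taxonomy against a combined model, and the 2D RSA-vs-confidence
histogram with count bands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from predstack.alphabet import CANONICAL_AA, AA_TO_INDEX
from predstack.errors import ConfigError, InputError
from predstack.formats_io import PredictionSet, SiteRecord

logger = logging.getLogger(__name__)

AA_CLASS_LABELS: tuple[str, ...] = (
    "aliphatic", "aromatic", "polar", "positive", "negative", "unique",
)

#: Default amino-acid class map. Histidine sits in "positive" by default;
#: pass a custom map to move it. "unique" is glycine and proline.
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{aa: "aliphatic" for aa in "AVLIM"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "polar" for aa in "STNQC"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "unique" for aa in "GP"},
}

AGREEMENT_LABELS: tuple[str, ...] = (
    "ALL", "SEQUENCE_ONLY", "STRUCTURE_ONLY", "MIXED", "NONE",
)


def validate_class_map(class_map: Mapping[str, str]) -> None:
    """Require a total map over the 20 canonical amino acids."""
    missing = [aa for aa in CANONICAL_AA if aa not in class_map]
    if missing:
        raise ConfigError(f"class map missing amino acid(s): {''.join(missing)}")
    bad = {aa: c for aa, c in class_map.items() if c not in AA_CLASS_LABELS}
    if bad:
        raise ConfigError(f"unknown class label(s): {bad}")


def load_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (amino_acid, class) TSV class map."""
    frame = pd.read_csv(path, sep="\t")
    if not {"amino_acid", "class"} <= set(frame.columns):
        raise ConfigError(f"{path}: expected columns amino_acid, class")
    class_map = dict(zip(frame["amino_acid"], frame["class"]))
    validate_class_map(class_map)
    return class_map


def top_prediction(v: np.ndarray) -> tuple[str, float]:
    """Argmax amino acid and its probability; ties break by alphabet order."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite probability vector")
    idx = int(np.argmax(v))  # first maximum == alphabetical tie-break
    return CANONICAL_AA[idx], float(v[idx])


@dataclass
class AccuracyResult:
    fraction: float
    n_correct: int
    n_sites: int


def _evaluable(labels: Sequence[SiteRecord]) -> list[SiteRecord]:
    return [s for s in labels if s.wt_aa in AA_TO_INDEX]


def protein_accuracy(
    pset: PredictionSet,
    labels: Sequence[SiteRecord],
    model_id: str,
    protein_id: str,
) -> AccuracyResult:
    """Fraction of a protein's sites whose top prediction equals wildtype."""
    sites = [s for s in _evaluable(labels) if s.protein_id == protein_id]
    if not sites:
        warnings.warn(f"no evaluable sites for protein {protein_id}", stacklevel=2)
        return AccuracyResult(float("nan"), 0, 0)
    n_correct = 0
    for site in sites:
        key = (site.protein_id, site.position, model_id)
        if key not in pset.entries:
            raise InputError(f"missing prediction for {key}")
        aa, _ = top_prediction(pset.entries[key])
        n_correct += aa == site.wt_aa
    return AccuracyResult(n_correct / len(sites), n_correct, len(sites))


def per_protein_accuracies(
    pset: PredictionSet, labels: Sequence[SiteRecord], model_id: str
) -> dict[str, AccuracyResult]:
    proteins = sorted({s.protein_id for s in _evaluable(labels)})
    return {pid: protein_accuracy(pset, labels, model_id, pid) for pid in proteins}


def class_accuracy(
    pset: PredictionSet,
    labels: Sequence[SiteRecord],
    model_id: str,
    class_map: Mapping[str, str] | None = None,
    burial: str | None = None,
    burial_threshold: float = 0.2,
) -> dict[str, AccuracyResult]:
    """Pooled-over-proteins accuracy per amino-acid class.

    With burial="buried"/"exposed", only sites on that side of
    burial_threshold are pooled (sites lacking RSA are skipped).
    Classes with zero sites get fraction NaN.
    """
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    validate_class_map(class_map)
    counts = {c: [0, 0] for c in AA_CLASS_LABELS}  # class -> [correct, total]
    for site in _evaluable(labels):
        if burial is not None:
            if site.rsa is None:
                continue
            is_buried = site.rsa < burial_threshold
            if (burial == "buried") != is_buried:
                continue
        cls = class_map[site.wt_aa]
        aa, _ = top_prediction(pset.entries[(site.protein_id, site.position, model_id)])
        counts[cls][0] += aa == site.wt_aa
        counts[cls][1] += 1
    return {
        c: AccuracyResult(k / n if n else float("nan"), k, n)
        for c, (k, n) in counts.items()
    }


def accuracy_correlation(
    acc_a: Sequence[float], acc_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and two-sided p between two per-protein accuracy vectors."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("accuracy vectors must cover the same proteins")
    if a.size < 3:
        raise InputError(f"need at least 3 proteins, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant accuracy vector: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass(frozen=True)
class AgreementCategory:
    label: str
    agreeing_models: frozenset[str]


def classify_agreement(
    individual_tops: Mapping[str, str],
    combined_top: str,
    model_types: Mapping[str, str],
) -> AgreementCategory:
    """Five-way category of which individual models match the combined top.

    all four -> ALL; none -> NONE; a nonempty subset of the sequence pair ->
    SEQUENCE_ONLY; of the structure pair -> STRUCTURE_ONLY; otherwise MIXED.
    """
    if len(individual_tops) != 4:
        raise InputError(f"expected 4 individual models, got {len(individual_tops)}")
    for mid in individual_tops:
        if model_types.get(mid) not in ("structure", "sequence"):
            raise ConfigError(f"unknown model type for {mid!r}")
    agreeing = frozenset(m for m, aa in individual_tops.items() if aa == combined_top)
    types = {model_types[m] for m in agreeing}
    if len(agreeing) == 4:
        label = "ALL"
    elif not agreeing:
        label = "NONE"
    elif types == {"sequence"}:
        label = "SEQUENCE_ONLY"
    elif types == {"structure"}:
        label = "STRUCTURE_ONLY"
    else:
        label = "MIXED"
    return AgreementCategory(label, agreeing)


@dataclass
class AgreementSummary:
    """Per-category accuracy of the combined prediction and site share."""

    accuracy: dict[str, float]
    proportion: dict[str, float]
    count: dict[str, int]


def agreement_summary(
    pset: PredictionSet,
    labels: Sequence[SiteRecord],
    model_types: Mapping[str, str],
    combined_id: str = "combined",
) -> AgreementSummary:
    individual_ids = [m for m in pset.model_ids if m != combined_id]
    if combined_id not in pset.model_ids or len(individual_ids) != 4:
        raise InputError(
            f"need four individual models plus {combined_id!r}; have {pset.model_ids}"
        )
    correct = {c: 0 for c in AGREEMENT_LABELS}
    count = {c: 0 for c in AGREEMENT_LABELS}
    for site in _evaluable(labels):
        combined_top, _ = top_prediction(
            pset.entries[(site.protein_id, site.position, combined_id)]
        )
        tops = {
            mid: top_prediction(pset.entries[(site.protein_id, site.position, mid)])[0]
            for mid in individual_ids
        }
        cat = classify_agreement(tops, combined_top, model_types)
        count[cat.label] += 1
        correct[cat.label] += combined_top == site.wt_aa
    total = sum(count.values())
    return AgreementSummary(
        accuracy={c: (correct[c] / count[c] if count[c] else float("nan"))
                  for c in AGREEMENT_LABELS},
        proportion={c: (count[c] / total if total else float("nan"))
                    for c in AGREEMENT_LABELS},
        count=count,
    )


COUNT_BANDS: tuple[tuple[int, float, str], ...] = (
    (1, 25, "1-25"), (26, 50, "26-50"), (51, 75, "51-75"), (76, float("inf"), ">75"),
)


def count_band(n: int) -> str:
    for lo, hi, label in COUNT_BANDS:
        if lo <= n <= hi:
            return label
    return ""


@dataclass
class RsaConfidenceHistogram:
    counts: np.ndarray           # (n_rsa_bins, n_conf_bins) integer counts
    rsa_edges: np.ndarray
    confidence_edges: np.ndarray
    bands: np.ndarray            # same shape as counts, band label strings
    n_skipped: int = 0


def rsa_confidence_histogram(
    sites: Sequence[SiteRecord],
    confidences: Sequence[float],
    rsa_bin_width: float = 0.05,
    confidence_bin_width: float = 0.05,
) -> RsaConfidenceHistogram:
    """2D histogram over (RSA, confidence) with half-open bins.

    Bins are [lo, hi) except the last bin on each axis, which is closed.
    Sites without RSA are skipped (counted in n_skipped). Each populated
    cell is labeled with its count band (1-25, 26-50, 51-75, >75).
    """
    if len(sites) != len(confidences):
        raise InputError("sites and confidences differ in length")
    rsa_vals, conf_vals, n_skipped = [], [], 0
    for site, conf in zip(sites, confidences):
        if site.rsa is None:
            n_skipped += 1
        else:
            rsa_vals.append(site.rsa)
            conf_vals.append(conf)
    if n_skipped:
        logger.info("rsa_confidence_histogram: skipped %d site(s) without RSA", n_skipped)

    rsa_max = max(rsa_vals, default=1.0)
    # one bin past the max so the top value sits in a half-open bin
    n_rsa_bins = int(np.floor(round(rsa_max / rsa_bin_width, 9))) + 1
    # round edges so values sitting exactly on a bin boundary land in the
    # upper (half-open) bin despite float accumulation
    rsa_edges = np.round(np.arange(n_rsa_bins + 1) * rsa_bin_width, 12)
    n_conf_bins = max(1, int(np.ceil(round(1.0 / confidence_bin_width, 9))))
    conf_edges = np.round(np.arange(n_conf_bins + 1) * confidence_bin_width, 12)

    counts, _, _ = np.histogram2d(rsa_vals, conf_vals, bins=[rsa_edges, conf_edges])
    counts = counts.astype(int)
    bands = np.vectorize(count_band, otypes=[object])(counts)
    return RsaConfidenceHistogram(counts, rsa_edges, conf_edges, bands, n_skipped)


@dataclass
class EvaluationReport:
    """All report tables for one panel of models."""

    per_protein_accuracy: dict[str, dict[str, AccuracyResult]]  # model -> protein -> acc
    per_class_accuracy: dict[str, dict[str, AccuracyResult]]    # model -> class -> acc
    correlation: dict[tuple[str, str], tuple[float, float]]     # (a, b) -> (r, p)
    agreement: AgreementSummary | None
    rsa_confidence: dict[str, RsaConfidenceHistogram] = field(default_factory=dict)


def evaluate_panel(
    pset: PredictionSet,
    labels: Sequence[SiteRecord],
    model_types: Mapping[str, str] | None = None,
    class_map: Mapping[str, str] | None = None,
    combined_id: str = "combined",
    rsa_bin_width: float = 0.05,
    confidence_bin_width: float = 0.05,
    agreement_model_ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Run the full evaluation battery over every model in pset.

    The agreement table is produced only when the combined model plus four
    typed individual models are available (agreement_model_ids selects the
    individuals when pset holds extra models such as naive baselines).
    """
    per_protein = {m: per_protein_accuracies(pset, labels, m) for m in pset.model_ids}
    per_class = {m: class_accuracy(pset, labels, m, class_map) for m in pset.model_ids}

    correlation: dict[tuple[str, str], tuple[float, float]] = {}
    proteins = sorted({s.protein_id for s in _evaluable(labels)})
    if len(proteins) >= 3:
        for i, ma in enumerate(pset.model_ids):
            for mb in pset.model_ids[i + 1:]:
                va = [per_protein[ma][p].fraction for p in proteins]
                vb = [per_protein[mb][p].fraction for p in proteins]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    correlation[(ma, mb)] = accuracy_correlation(va, vb)

    agreement = None
    if model_types is not None and combined_id in pset.model_ids:
        individuals = (list(agreement_model_ids) if agreement_model_ids is not None
                       else [m for m in pset.model_ids
                             if model_types.get(m) in ("structure", "sequence")])
        if len(individuals) == 4:
            ag_pset = PredictionSet(model_ids=individuals + [combined_id])
            ag_pset.entries = {k: v for k, v in pset.entries.items()
                               if k[2] in ag_pset.model_ids}
            agreement = agreement_summary(ag_pset, labels, model_types, combined_id)

    rsa_hists: dict[str, RsaConfidenceHistogram] = {}
    evaluable = _evaluable(labels)
    if any(s.rsa is not None for s in evaluable):
        for mid in pset.model_ids:
            confs = [top_prediction(pset.entries[(s.protein_id, s.position, mid)])[1]
                     for s in evaluable]
            rsa_hists[mid] = rsa_confidence_histogram(
                evaluable, confs, rsa_bin_width, confidence_bin_width)

    return EvaluationReport(per_protein, per_class, correlation, agreement, rsa_hists)


def write_report(report: EvaluationReport, out_dir: str | Path) -> list[Path]:
    """Emit the report as TSV tables; returns the files written.

    Float cells use a fixed %.12g format so identical reports are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def fmt(x: float) -> str:
        return format(x, ".12g")

    path = out_dir / "per_protein_accuracy.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("model_id\tprotein_id\taccuracy\tn_correct\tn_sites\n")
        for mid in sorted(report.per_protein_accuracy):
            for pid, acc in sorted(report.per_protein_accuracy[mid].items()):
                fh.write(f"{mid}\t{pid}\t{fmt(acc.fraction)}\t{acc.n_correct}\t{acc.n_sites}\n")
    written.append(path)

    path = out_dir / "class_accuracy.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("model_id\taa_class\taccuracy\tn_correct\tn_sites\n")
        for mid in sorted(report.per_class_accuracy):
            for cls in AA_CLASS_LABELS:
                acc = report.per_class_accuracy[mid][cls]
                fh.write(f"{mid}\t{cls}\t{fmt(acc.fraction)}\t{acc.n_correct}\t{acc.n_sites}\n")
    written.append(path)

    path = out_dir / "correlation_matrix.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("model_a\tmodel_b\tpearson_r\tp_value\n")
        for (ma, mb), (r, p) in sorted(report.correlation.items()):
            fh.write(f"{ma}\t{mb}\t{fmt(r)}\t{fmt(p)}\n")
    written.append(path)

    if report.agreement is not None:
        path = out_dir / "agreement_table.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("category\taccuracy\tproportion\tcount\n")
            for cat in AGREEMENT_LABELS:
                fh.write(f"{cat}\t{fmt(report.agreement.accuracy[cat])}\t"
                         f"{fmt(report.agreement.proportion[cat])}\t"
                         f"{report.agreement.count[cat]}\n")
        written.append(path)

    if report.rsa_confidence:
        path = out_dir / "rsa_confidence_histogram.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("model_id\trsa_lo\trsa_hi\tconfidence_lo\tconfidence_hi\tcount\tband\n")
            for mid in sorted(report.rsa_confidence):
                hist = report.rsa_confidence[mid]
                for i in range(hist.counts.shape[0]):
                    for j in range(hist.counts.shape[1]):
                        n = hist.counts[i, j]
                        if n == 0:
                            continue
                        fh.write(f"{mid}\t{fmt(hist.rsa_edges[i])}\t{fmt(hist.rsa_edges[i + 1])}\t"
                                 f"{fmt(hist.confidence_edges[j])}\t{fmt(hist.confidence_edges[j + 1])}\t"
                                 f"{n}\t{hist.bands[i, j]}\n")
        written.append(path)

    return written
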