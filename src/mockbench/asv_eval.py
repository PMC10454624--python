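"""ASV-level evaluation against mock genomes of known taxonomy.

Each denoised amplicon sequence variant (ASV) is aligned to the mock
reference genomes; hits are filtered at identity >= 97% and query coverage
>= 90% and the best survivor is kept.  An ASV landing on an annotated 16S
gene is a true positive when its taxonomic call matches the genome's known
lineage at the evaluated rank (after alias mapping between reference
taxonomies), a false positive when the call is present but wrong, and a
false negative when the call is blank at that rank.  An ASV landing outside
every 16S region is a true negative; ASVs with no surviving hit are
"unaligned" background noise and are excluded from the confusion matrix.

Precision, accuracy and recall come from the (optionally read-weighted)
confusion matrix, and a ROC/AUC is computed over on-gene ASVs using the
classifier confidence as the score.

Genome scanning uses banded infix edit-distance alignment (edlib), after
which each raw alignment is trimmed to its maximal-scoring local segment
under BLASTN-like affine scores (match +2, mismatch -3, gap open 5, gap
extend 2); identity and query coverage are computed on the trimmed segment.
Precomputed BLAST outfmt-6 hits can be supplied instead.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .io_formats import GenomeAnnotation, TaxonomicLineage, normalize_label
from .read_stratify import reverse_complement

MATCH_SCORE = 2
MISMATCH_SCORE = -3
GAP_OPEN = 5    # penalty charged for the first base of a gap (in addition to extend)
GAP_EXTEND = 2

#: Known label discrepancies between mock certificates and reference
#: taxonomies (e.g. SILVA): each pair is treated as the same taxon.
DEFAULT_ALIASES: dict[str, str] = {
    "clostridium sensu stricto 1": "clostridium",
    "actinomyces": "schaalia",
    "escherichia-shigella": "escherichia",
}

LABELS = ("TP", "FP", "TN", "FN")


@dataclass
class AsvRecord:
    """One ASV with its abundance, taxonomic call and optional confidence."""

    asv_id: str
    sequence: str
    read_count: float = 1.0
    call: TaxonomicLineage = field(default_factory=TaxonomicLineage)
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError(f"{self.asv_id}: negative read count")


@dataclass(frozen=True)
class Hit:
    """A filtered alignment of one ASV to one genome."""

    asv_id: str
    genome_id: str
    identity_pct: float
    query_coverage_pct: float
    subject_span: tuple[int, int]  # 0-based half-open on the genome
    bitscore: float


@dataclass(frozen=True)
class AsvLabel:
    asv_id: str
    label: str  # TP / FP / TN / FN / unaligned
    rank: str


@dataclass
class ConfusionMatrix:
    tp: float = 0.0
    fp: float = 0.0
    tn: float = 0.0
    fn: float = 0.0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix entries must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


# ---------------------------------------------------------------------------
# Alignment

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _expand_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def _trim_local(ops: list[tuple[str, int]]) -> tuple[dict[str, int], int, int, int]:
    """Maximal-scoring contiguous segment of an alignment path.

    Expands the path into per-column scores (affine gap runs charged
    open+extends on their first column) and runs Kadane's maximum-subarray
    over it.  Returns (op counts, score, leading target offset, leading
    query offset) of the chosen segment.
    """
    cols: list[tuple[str, int]] = []   # (op, column score)
    for op, n in ops:
        if op == "=":
            cols += [("=", MATCH_SCORE)] * n
        elif op in ("X", "M"):
            cols += [("X", MISMATCH_SCORE)] * n
        else:  # I or D gap run
            cols.append((op, -(GAP_OPEN + GAP_EXTEND)))
            cols += [(op, -GAP_EXTEND)] * (n - 1)

    best = (0, 0, 0)  # score, start, end (empty segment allowed)
    run_score, run_start = 0, 0
    for i, (_, s) in enumerate(cols):
        if run_score <= 0:
            run_score, run_start = s, i
        else:
            run_score += s
        if run_score > best[0]:
            best = (run_score, run_start, i + 1)
    score, start, end = best

    counts = {"=": 0, "X": 0, "I": 0, "D": 0}
    for op, _ in cols[start:end]:
        counts[op] += 1
    t_off = sum(1 for op, _ in cols[:start] if op in ("=", "X", "D"))
    q_off = sum(1 for op, _ in cols[:start] if op in ("=", "X", "I"))
    return counts, score, t_off, q_off


def _align_one(query: str, genome_id: str, target: str, asv_id: str,
               max_divergence: float) -> Hit | None:
    k = max(1, int(max_divergence * len(query)))
    res = edlib.align(query, target, mode="HW", task="path", k=k)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t_start = res["locations"][0][0]
    counts, score, t_off, _ = _trim_local(_expand_cigar(res["cigar"]))
    aln_len = counts["="] + counts["X"] + counts["I"] + counts["D"]
    if aln_len == 0 or score <= 0:
        return None
    identity = 100.0 * counts["="] / aln_len
    qcov = 100.0 * (counts["="] + counts["X"] + counts["I"]) / len(query)
    span = (t_start + t_off, t_start + t_off + counts["="] + counts["X"] + counts["D"])
    return Hit(asv_id, genome_id, identity, qcov, span, float(score))


def align_asv(asv_sequence: str, genomes: Mapping[str, str],
              asv_id: str = "asv", max_divergence: float = 0.30) -> list[Hit]:
    """Align one ASV against every genome (both strands), best hit per genome.

    ``max_divergence`` bounds the banded search: candidate placements with
    an edit distance above that fraction of the query length are not
    reported (they could never approach the 97%/90% filters anyway).
    Deterministic given inputs.
    """
    if not asv_sequence:
        raise ValueError("empty ASV sequence")
    query = asv_sequence.upper()
    rc = reverse_complement(query)
    hits = []
    for genome_id in sorted(genomes):
        target = genomes[genome_id].upper()
        cands = [h for q in (query, rc)
                 if (h := _align_one(q, genome_id, target, asv_id,
                                     max_divergence)) is not None]
        if cands:
            hits.append(max(cands, key=lambda h: (h.bitscore, h.identity_pct)))
    return hits


def hits_from_outfmt6(df: pd.DataFrame,
                      query_lengths: Mapping[str, int]) -> dict[str, list[Hit]]:
    """Convert a BLAST outfmt-6 table into per-ASV Hit lists.

    Query coverage is (aligned query span)/(query length); subject spans are
    converted from 1-based inclusive (strand-ordered) to 0-based half-open.
    """
    out: dict[str, list[Hit]] = {}
    for row in df.itertuples(index=False):
        qlen = query_lengths.get(row.qseqid)
        if qlen is None:
            raise ValueError(f"unknown query length for {row.qseqid!r}")
        qcov = 100.0 * (abs(int(row.qend) - int(row.qstart)) + 1) / qlen
        s, e = sorted((int(row.sstart), int(row.send)))
        hit = Hit(str(row.qseqid), str(row.sseqid), float(row.pident),
                  qcov, (s - 1, e), float(row.bitscore))
        out.setdefault(hit.asv_id, []).append(hit)
    return out


def best_hit(hits: Sequence[Hit], min_identity: float = 97.0,
             min_qcov: float = 90.0) -> Hit | None:
    """Best hit after identity/coverage filtering.

    Survivors are ranked by bitscore, then identity, then genome id
    (lexicographically smallest wins), making the choice deterministic.
    """
    survivors = [h for h in hits
                 if h.identity_pct >= min_identity
                 and h.query_coverage_pct >= min_qcov]
    if not survivors:
        return None
    return min(survivors,
               key=lambda h: (-h.bitscore, -h.identity_pct, h.genome_id))


# ---------------------------------------------------------------------------
# Labelling


def _apply_alias(label: str, aliases: Mapping[str, str]) -> str:
    return aliases.get(label, label)


def _overlaps_any_ssu(span: tuple[int, int],
                      annotation: GenomeAnnotation) -> bool:
    s, e = span
    return any(min(e, g.end) > max(s, g.start) for g in annotation.ssu_genes)


def label_asv(asv: AsvRecord, hit: Hit | None,
              annotations: Mapping[str, GenomeAnnotation],
              truth: Mapping[str, TaxonomicLineage],
              rank: str,
              aliases: Mapping[str, str] | None = None) -> AsvLabel:
    """Assign TP/FP/TN/FN (or unaligned) to one ASV at one rank.

    ``truth`` maps genome_id to the known lineage of the mock member the
    genome belongs to.  Alias mapping is applied symmetrically to the call
    and the truth label before comparison.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    if hit is None:
        return AsvLabel(asv.asv_id, "unaligned", rank)
    if hit.genome_id not in truth:
        raise ValueError(f"no truth lineage for genome {hit.genome_id!r}")
    if not _overlaps_any_ssu(hit.subject_span, annotations[hit.genome_id]):
        return AsvLabel(asv.asv_id, "TN", rank)
    call = _apply_alias(asv.call.normalized(rank), aliases)
    true_label = _apply_alias(truth[hit.genome_id].normalized(rank), aliases)
    if not call:
        return AsvLabel(asv.asv_id, "FN", rank)
    return AsvLabel(asv.asv_id, "TP" if call == true_label else "FP", rank)


def confusion(labels: Iterable[AsvLabel],
              weights: Mapping[str, float] | None = None) -> ConfusionMatrix:
    """Sum (read-count) weights per label; unit weights when None.

    Unaligned ASVs must be excluded by the caller (they have no defined
    cell); passing one raises.
    """
    cm = ConfusionMatrix()
    for lab in labels:
        if lab.label not in LABELS:
            raise ValueError(f"{lab.asv_id}: label {lab.label!r} has no "
                             "confusion-matrix cell")
        w = 1.0 if weights is None else float(weights.get(lab.asv_id, 0.0))
        if lab.label == "TP":
            cm.tp += w
        elif lab.label == "FP":
            cm.fp += w
        elif lab.label == "TN":
            cm.tn += w
        else:
            cm.fn += w
    return cm


def prf(cm: ConfusionMatrix) -> tuple[float | None, float | None, float | None]:
    """(precision, accuracy, recall) as percentages.

    A metric whose denominator is zero is returned as None with a warning.
    """
    def ratio(num: float, den: float, name: str) -> float | None:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=2)
            return None
        return 100.0 * num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    accuracy = ratio(cm.tp + cm.tn, cm.total, "accuracy")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    return precision, accuracy, recall


def roc_auc(labels: Iterable[AsvLabel],
            scores: Mapping[str, float],
            weights: Mapping[str, float] | None = None,
            ) -> tuple[pd.DataFrame, float | None]:
    """ROC curve and AUC over on-gene ASVs.

    Positives are TP-labelled ASVs; negatives are FP/FN-labelled ones
    (correct vs incorrect classification among ASVs that hit a 16S gene).
    Scores are classifier confidences; ties are handled by thresholding on
    distinct score values, and the AUC equals the normalized Mann-Whitney
    U statistic (ties counted half).  Returns (curve, None) when either
    class is absent or no scores are available.
    """
    y, s, w = [], [], []
    for lab in labels:
        if lab.label not in ("TP", "FP", "FN"):
            continue
        score = scores.get(lab.asv_id)
        if score is None or np.isnan(score):
            continue
        y.append(1 if lab.label == "TP" else 0)
        s.append(float(score))
        w.append(1.0 if weights is None else float(weights.get(lab.asv_id, 0.0)))
    if not y:
        # no confidences: only the trivial single-threshold point exists
        point = pd.DataFrame({"fpr": [1.0], "tpr": [1.0], "threshold": [np.nan]})
        return point, None
    if len(set(y)) < 2:
        return pd.DataFrame(columns=["fpr", "tpr", "threshold"]), None
    y_arr, s_arr, w_arr = map(np.asarray, (y, s, w))
    fpr, tpr, thr = roc_curve(y_arr, s_arr, sample_weight=w_arr)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    auc = float(roc_auc_score(y_arr, s_arr, sample_weight=w_arr))
    return curve, auc


# ---------------------------------------------------------------------------
# End-to-end convenience


@dataclass
class AsvEvaluation:
    """Bundle of labels, confusion matrix, metrics and ROC for one rank."""

    rank: str
    labels: list[AsvLabel]
    confusion: ConfusionMatrix
    precision: float | None
    accuracy: float | None
    recall: float | None
    roc: pd.DataFrame
    auc: float | None
    n_unaligned: int

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.asv_id, l.label, l.rank) for l in self.labels],
            columns=["asv_id", "label", "rank"],
        )

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "rank": self.rank,
            "tp": self.confusion.tp, "fp": self.confusion.fp,
            "tn": self.confusion.tn, "fn": self.confusion.fn,
            "precision_pct": self.precision, "accuracy_pct": self.accuracy,
            "recall_pct": self.recall, "auc": self.auc,
            "n_unaligned": self.n_unaligned,
        }])


def evaluate_asvs(asvs: Sequence[AsvRecord],
                  genomes: Mapping[str, str],
                  annotations: Mapping[str, GenomeAnnotation],
                  truth: Mapping[str, TaxonomicLineage],
                  rank: str = "species",
                  min_identity: float = 97.0,
                  min_qcov: float = 90.0,
                  aliases: Mapping[str, str] | None = None,
                  read_weighted: bool = True,
                  hits: Mapping[str, Sequence[Hit]] | None = None,
                  ) -> AsvEvaluation:
    """Run the full ASV evaluation at one rank.

    When ``hits`` (e.g. parsed BLAST outfmt-6) is given, the bundled
    aligner is skipped.
    """
    weights = {a.asv_id: a.read_count for a in asvs} if read_weighted else None
    scores = {a.asv_id: a.confidence for a in asvs if a.confidence is not None}

    labels: list[AsvLabel] = []
    for asv in asvs:
        asv_hits = hits.get(asv.asv_id, []) if hits is not None \
            else align_asv(asv.sequence, genomes, asv.asv_id)
        best = best_hit(asv_hits, min_identity, min_qcov)
        labels.append(label_asv(asv, best, annotations, truth, rank, aliases))

    aligned = [l for l in labels if l.label != "unaligned"]
    cm = confusion(aligned, weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, accuracy, recall = prf(cm)
    curve, auc = roc_auc(aligned, scores, weights)
    return AsvEvaluation(
        rank=rank, labels=labels, confusion=cm,
        precision=precision, accuracy=accuracy, recall=recall,
        roc=curve, auc=auc,
        n_unaligned=len(labels) - len(aligned),
    )
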