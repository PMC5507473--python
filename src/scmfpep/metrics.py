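"""Profile evaluation: experimental profiles from sequences and seven metrics.

A predicted specificity profile is scored against an experimental one with
cosine similarity, Frobenius distance, average absolute distance (AAD),
per-position Jensen-Shannon divergence with an empirical p-value, a
tolerated-amino-acid ranking AUC, the Score Sequence AUC Loss (SSAL) on
recognised/non-recognised sequence sets, and information content in bits.

For the identity pair the metrics hit their perfect extremes (cosine 1,
distances 0, AUC 1, SSAL 0); for two profiles with disjoint single-amino-
acid point masses at every position they hit the opposite extremes
(cosine 0, Frobenius sqrt(2n), JSD 1, bits difference log2(20) ~ 4.32).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import rel_entr
from scipy.stats import rankdata

from .interaction_model import (
    AA_INDEX,
    N_AA,
    SequenceSet,
    SpecificityProfile,
    ValidationError,
)

__all__ = [
    "MetricReport",
    "profile_from_sequences",
    "cosine_similarity",
    "frobenius_distance",
    "aad",
    "jsd",
    "profile_jsd",
    "jsd_pvalue",
    "positional_auc",
    "score_sequence",
    "sequence_roc_auc",
    "ssal",
    "information_content",
    "bits_difference",
    "evaluate_profiles",
]

#: Pseudo-frequency added before taking logs when scoring sequences.
SCORE_EPSILON = 1e-6


def profile_from_sequences(seqs: SequenceSet, dedupe: bool) -> SpecificityProfile:
    """Column amino-acid frequencies of an aligned peptide set.

    ``dedupe=True`` removes exact duplicate sequences first (the convention
    for protease cleavage sets); ``dedupe=False`` keeps multiplicity (the
    convention for peptide-recognition-domain binding sets).
    """
    if not seqs.records:
        raise ValidationError("empty sequence set")
    n = len(seqs.records[0][1])
    for rec_id, seq in seqs.records:
        if len(seq) != n:
            raise ValidationError(
                f"record '{rec_id}' has length {len(seq)}, expected {n}"
            )
    sequences = seqs.sequences
    if dedupe:
        sequences = list(dict.fromkeys(sequences))  # order-preserving
    counts = np.zeros((n, N_AA))
    for seq in sequences:
        for i, aa in enumerate(seq):
            counts[i, AA_INDEX[aa]] += 1
    return SpecificityProfile(counts / len(sequences))


def _check_shapes(pred: SpecificityProfile, exp: SpecificityProfile) -> None:
    if pred.freq.shape != exp.freq.shape:
        raise ValidationError(
            f"profile shapes differ: {pred.freq.shape} vs {exp.freq.shape}"
        )


def cosine_similarity(pred: SpecificityProfile, exp: SpecificityProfile) -> float:
    """Cosine of the two flattened N x 20 frequency vectors, in [0, 1]."""
    _check_shapes(pred, exp)
    a, b = pred.freq.ravel(), exp.freq.ravel()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def frobenius_distance(pred: SpecificityProfile, exp: SpecificityProfile) -> float:
    _check_shapes(pred, exp)
    return float(np.linalg.norm(pred.freq - exp.freq))


def aad(pred: SpecificityProfile, exp: SpecificityProfile) -> float:
    """Average absolute distance: mean |difference| over all N x 20 entries."""
    _check_shapes(pred, exp)
    return float(np.mean(np.abs(pred.freq - exp.freq)))


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence between two distributions, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    kl_pm = rel_entr(p, m).sum() / np.log(2)
    kl_qm = rel_entr(q, m).sum() / np.log(2)
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def profile_jsd(pred: SpecificityProfile, exp: SpecificityProfile) -> tuple[list[float], float]:
    """Per-position base-2 JSD and its mean over positions."""
    _check_shapes(pred, exp)
    per_pos = [jsd(pred.freq[i], exp.freq[i]) for i in range(pred.n_positions)]
    return per_pos, float(np.mean(per_pos))


def jsd_pvalue(
    exp_position: np.ndarray,
    observed_jsd: float,
    n_random: int = 100_000,
    seed: int = 0,
) -> float:
    """Empirical p-value of a positional JSD score.

    Random position profiles are drawn uniformly from the 20-simplex
    (symmetric Dirichlet with concentration 1) and scored against the
    experimental distribution; the add-one estimator
    ``(1 + #{random JSD <= observed}) / (n_random + 1)`` keeps the p-value
    strictly positive and makes 1/(n_random+1) the minimum attainable.
    """
    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    q = np.asarray(exp_position, dtype=float)
    rng = np.random.default_rng(seed)
    randoms = rng.dirichlet(np.ones(N_AA), size=n_random)
    # Vectorised base-2 JSD of each random row against q.
    m = 0.5 * (randoms + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(randoms > 0, randoms * np.log2(randoms / m), 0.0).sum(axis=1)
        kl_qm = np.where(q > 0, q * np.log2(q / m), 0.0).sum(axis=1)
    scores = 0.5 * kl_pm + 0.5 * kl_qm
    return float((1 + np.count_nonzero(scores <= observed_jsd)) / (n_random + 1))


def _mann_whitney_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC = P(pos > neg) + 0.5 * P(pos == neg), via midranks."""
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    ranks = rankdata(np.concatenate([pos_scores, neg_scores]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def positional_auc(
    pred: SpecificityProfile,
    exp: SpecificityProfile,
    tolerated_cutoff: float = 0.1,
) -> float:
    """Ranking AUC of tolerated amino acids, averaged over scorable positions.

    Per position, amino acids with experimental frequency >= cutoff are the
    positive class; the AUC is the Mann-Whitney statistic of the predicted
    frequencies (ties counted half).  Positions lacking either class are
    skipped; if every position is skipped the AUC is undefined and a
    ValidationError explains why.
    """
    _check_shapes(pred, exp)
    aucs = []
    for i in range(pred.n_positions):
        positive = exp.freq[i] >= tolerated_cutoff
        if positive.all() or not positive.any():
            continue
        aucs.append(_mann_whitney_auc(pred.freq[i][positive], pred.freq[i][~positive]))
    if not aucs:
        raise ValidationError(
            "AUC undefined: no position has both tolerated (freq >= "
            f"{tolerated_cutoff}) and non-tolerated amino acids"
        )
    return float(np.mean(aucs))


def score_sequence(profile: SpecificityProfile, seq: str) -> float:
    """Log-likelihood-style score: sum_i log2(freq(i, seq_i) + epsilon)."""
    if len(seq) != profile.n_positions:
        raise ValidationError(
            f"sequence length {len(seq)} != profile positions {profile.n_positions}"
        )
    try:
        idx = [AA_INDEX[aa] for aa in seq]
    except KeyError as exc:
        raise ValidationError(f"non-canonical letter {exc} in sequence") from exc
    return float(
        np.log2(profile.freq[np.arange(len(seq)), idx] + SCORE_EPSILON).sum()
    )


def sequence_roc_auc(
    profile: SpecificityProfile,
    positives: SequenceSet,
    negatives: SequenceSet,
) -> float:
    """Mann-Whitney AUC of profile scores: recognised vs non-recognised."""
    if not positives.records or not negatives.records:
        raise ValidationError("both sequence classes must be non-empty")
    pos = np.array([score_sequence(profile, s) for s in positives.sequences])
    neg = np.array([score_sequence(profile, s) for s in negatives.sequences])
    return _mann_whitney_auc(pos, neg)


def ssal(
    pred: SpecificityProfile,
    exp: SpecificityProfile,
    positives: SequenceSet,
    negatives: SequenceSet,
) -> float:
    """Score Sequence AUC Loss: how much discrimination the prediction loses.

    The drop in recognised-vs-non-recognised AUC when sequences are scored
    by the predicted instead of the experimental profile, clamped at zero
    (a prediction that discriminates better than the experimental profile
    scores a perfect 0).
    """
    return max(
        0.0,
        sequence_roc_auc(exp, positives, negatives)
        - sequence_roc_auc(pred, positives, negatives),
    )


def information_content(profile: SpecificityProfile) -> float:
    """Mean per-position information content: log2(20) - entropy, in bits."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(profile.freq > 0, profile.freq * np.log2(profile.freq), 0.0)
    entropy = -plogp.sum(axis=1)
    return float(np.mean(np.log2(N_AA) - entropy))


def bits_difference(pred: SpecificityProfile, exp: SpecificityProfile) -> float:
    """Predicted minus experimental information content (bits)."""
    return information_content(pred) - information_content(exp)


@dataclass
class MetricReport:
    """Full comparison of a predicted profile against an experimental one."""

    cosine: float
    frobenius: float
    aad: float
    jsd_per_position: list[float]
    jsd_pvalues: list[float]
    n_significant_positions: int
    significance_threshold: float
    jsd_profile: float
    auc: float | None
    auc_note: str | None
    ssal: float | None
    bits_pred: float
    bits_exp: float
    bits_diff: float

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(asdict(self), **kwargs)


def evaluate_profiles(
    pred: SpecificityProfile,
    exp: SpecificityProfile,
    positives: SequenceSet | None = None,
    negatives: SequenceSet | None = None,
    *,
    tolerated_cutoff: float = 0.1,
    n_random: int = 100_000,
    significance_threshold: float = 0.05,
    seed: int = 0,
) -> MetricReport:
    """Compute the full metric suite in one pass.

    SSAL requires both sequence sets and is reported as ``None`` without
    them.  JSD p-values use ``n_random`` simplex-uniform random profiles per
    position (seeded per position for reproducibility independent of N).
    """
    _check_shapes(pred, exp)
    per_pos, jsd_mean = profile_jsd(pred, exp)
    pvalues = [
        jsd_pvalue(exp.freq[i], per_pos[i], n_random=n_random, seed=seed + i)
        for i in range(exp.n_positions)
    ]
    try:
        auc_value: float | None = positional_auc(pred, exp, tolerated_cutoff)
        auc_note = None
    except ValidationError as exc:
        auc_value, auc_note = None, str(exc)
    ssal_value = (
        ssal(pred, exp, positives, negatives)
        if positives is not None and negatives is not None
        else None
    )
    bits_pred = information_content(pred)
    bits_exp = information_content(exp)
    return MetricReport(
        cosine=cosine_similarity(pred, exp),
        frobenius=frobenius_distance(pred, exp),
        aad=aad(pred, exp),
        jsd_per_position=per_pos,
        jsd_pvalues=pvalues,
        n_significant_positions=sum(p <= significance_threshold for p in pvalues),
        significance_threshold=significance_threshold,
        jsd_profile=jsd_mean,
        auc=auc_value,
        auc_note=auc_note,
        ssal=ssal_value,
        bits_pred=bits_pred,
        bits_exp=bits_exp,
        bits_diff=bits_pred - bits_exp,
    )
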