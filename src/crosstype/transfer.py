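"""Cross-species label transfer and its evaluation.

After training, labels are transferred by classifier swapping: species-A
cells are scored with the species-B classifier head and vice versa. Each
direction yields a row-normalized confusion matrix (true type x transferred
type); the two are averaged (one transposed) into a combined matrix whose
high entries indicate reciprocal cell-type matches. Against a ground-truth
type correspondence we report the average diagonal score (ADS) and the
recall, the fraction of corresponding pairs whose combined score is the
strict maximum of both its row and its column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_space import SharedFeatureMatrix
from .model import TrainedModel, classify, feature_order_hash


@dataclass
class TypeCorrespondence:
    """Ground-truth cell-type pairs plus species-specific types."""

    pairs: list[tuple[str, str]]
    species_specific_a: set[str] = field(default_factory=set)
    species_specific_b: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate correspondence pairs")
        paired_a = {a for a, _ in self.pairs}
        paired_b = {b for _, b in self.pairs}
        if paired_a & self.species_specific_a or paired_b & self.species_specific_b:
            raise ValueError("a type cannot be both paired and species-specific")


@dataclass
class MatchResult:
    """Directional confusion matrices, combined matrix, and summary metrics."""

    types_a: list[str]
    types_b: list[str]
    m_a_to_b: np.ndarray   # |T_A| x |T_B|, row-normalized
    m_b_to_a: np.ndarray   # |T_B| x |T_A|, row-normalized
    combined: np.ndarray   # |T_A| x |T_B|
    ads: float
    recall: float
    per_pair_scores: dict[tuple[str, str], float]
    transferred_a: pd.DataFrame | None = None  # cell_id, true_type, transferred_type, max_probability
    transferred_b: pd.DataFrame | None = None

    def combined_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.combined, index=self.types_a, columns=self.types_b)


def transfer_labels(model: TrainedModel, shared: SharedFeatureMatrix,
                    direction: str) -> pd.DataFrame:
    """Predict opposite-species types for one species' cells.

    ``direction`` is ``"a_to_b"`` (species-A cells through the B classifier)
    or ``"b_to_a"``. Argmax ties resolve to the lowest type index. Returns a
    frame with cell_id, true_type, transferred_type, max_probability.
    """
    if model.feature_ids and feature_order_hash(shared.feature_ids) != model.feature_hash:
        raise ValueError("feature-order hash mismatch between model and shared features")
    if direction == "a_to_b":
        opp_species, opp_types = "b", model.types_b
    elif direction == "b_to_a":
        opp_species, opp_types = "a", model.types_a
    else:
        raise ValueError(f"unknown direction {direction!r}")
    probs = classify(model, shared.values, opp_species)
    pred_idx = probs.argmax(axis=1)  # first index on exact ties
    n = shared.n_cells
    return pd.DataFrame({
        "cell_id": shared.cell_ids if shared.cell_ids else [str(i) for i in range(n)],
        "true_type": shared.cell_types if shared.cell_types else [""] * n,
        "transferred_type": [opp_types[i] for i in pred_idx],
        "max_probability": probs[np.arange(n), pred_idx],
    })


def confusion_normalized(true_types: list[str], transferred_types: list[str],
                         vocab_src: list[str], vocab_dst: list[str]) -> np.ndarray:
    """Row-normalized confusion matrix over fixed vocabularies.

    Entry (s, d) is the fraction of source cells of type s transferred to
    type d. Rows for types with no cells are all-zero.
    """
    pos_src = {t: i for i, t in enumerate(vocab_src)}
    pos_dst = {t: i for i, t in enumerate(vocab_dst)}
    M = np.zeros((len(vocab_src), len(vocab_dst)))
    for s, d in zip(true_types, transferred_types):
        if s not in pos_src:
            raise ValueError(f"unseen source label {s!r}")
        if d not in pos_dst:
            raise ValueError(f"unseen destination label {d!r}")
        M[pos_src[s], pos_dst[d]] += 1.0
    sums = M.sum(axis=1, keepdims=True)
    nonzero = sums[:, 0] > 0
    M[nonzero] /= sums[nonzero]
    return M


def combine(m_a_to_b: np.ndarray, m_b_to_a: np.ndarray) -> np.ndarray:
    """Average the two transfer directions: (M_AtoB + M_BtoA^T) / 2."""
    m_a_to_b = np.asarray(m_a_to_b, dtype=float)
    m_b_to_a = np.asarray(m_b_to_a, dtype=float)
    if m_a_to_b.shape != m_b_to_a.T.shape:
        raise ValueError(f"shape mismatch: {m_a_to_b.shape} vs {m_b_to_a.shape}^T")
    return (m_a_to_b + m_b_to_a.T) / 2.0


def ads(combined: np.ndarray, corr: TypeCorrespondence,
        types_a: list[str], types_b: list[str]) -> float:
    """Average diagonal score over ground-truth pairs.

    Species-specific types never appear in the pair list, so they are
    excluded by construction. A perfect reciprocal transfer scores 1.
    """
    if not corr.pairs:
        raise ValueError("empty correspondence pair list")
    ia = {t: i for i, t in enumerate(types_a)}
    ib = {t: i for i, t in enumerate(types_b)}
    return float(np.mean([combined[ia[a], ib[b]] for a, b in corr.pairs]))


def recall(combined: np.ndarray, corr: TypeCorrespondence,
           types_a: list[str], types_b: list[str]) -> float:
    """Fraction of pairs whose score is the strict row AND column maximum.

    Exact ties count as failure (conservative, deterministic).
    """
    if not corr.pairs:
        raise ValueError("empty correspondence pair list")
    ia = {t: i for i, t in enumerate(types_a)}
    ib = {t: i for i, t in enumerate(types_b)}
    hits = 0
    for a, b in corr.pairs:
        i, j = ia[a], ib[b]
        v = combined[i, j]
        row_others = np.delete(combined[i, :], j)
        col_others = np.delete(combined[:, j], i)
        if (row_others.size == 0 or v > row_others.max()) and \
           (col_others.size == 0 or v > col_others.max()):
            hits += 1
    return hits / len(corr.pairs)


def evaluate_transfer(model: TrainedModel,
                      shared_a: SharedFeatureMatrix,
                      shared_b: SharedFeatureMatrix,
                      corr: TypeCorrespondence) -> MatchResult:
    """Full evaluation: swap classifiers, build matrices, score ADS/recall.

    Matrix vocabularies are the union of the model's type sets and the
    correspondence's types, so types absent from one species appear as
    all-zero rows/columns rather than being dropped.
    """
    types_a = sorted(set(model.types_a)
                     | {a for a, _ in corr.pairs} | corr.species_specific_a)
    types_b = sorted(set(model.types_b)
                     | {b for _, b in corr.pairs} | corr.species_specific_b)

    tr_a = transfer_labels(model, shared_a, "a_to_b")
    tr_b = transfer_labels(model, shared_b, "b_to_a")
    m_ab = confusion_normalized(list(tr_a["true_type"]), list(tr_a["transferred_type"]),
                                types_a, types_b)
    m_ba = confusion_normalized(list(tr_b["true_type"]), list(tr_b["transferred_type"]),
                                types_b, types_a)
    comb = combine(m_ab, m_ba)
    ia = {t: i for i, t in enumerate(types_a)}
    ib = {t: i for i, t in enumerate(types_b)}
    per_pair = {(a, b): float(comb[ia[a], ib[b]]) for a, b in corr.pairs}
    return MatchResult(
        types_a, types_b, m_ab, m_ba, comb,
        ads(comb, corr, types_a, types_b),
        recall(comb, corr, types_a, types_b),
        per_pair, tr_a, tr_b,
    )
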