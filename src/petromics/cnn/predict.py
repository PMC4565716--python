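"""Tumor-level decisions by majority vote over slice samples.

Each triplet (or single slice) votes responder when its predicted
probability p(y = 1) exceeds 0.5; the tumor is called a responder when
the vote fraction (1/(m-2)) * sum I(y_hat = 1) is strictly greater than
0.5. A sample with p exactly 0.5 is a tie: during evaluation the protocol
scores it as *wrong* regardless of the true label, and at prediction time
it votes 0 — a tie carries no evidence for the positive call the vote
threshold demands. A tumor-level tie (vote fraction exactly 1/2) is
likewise resolved to non-responder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import TumorROI
from .data import build_singles, build_triplets, embed_roi
from .network import CNNModel

VOTE_THRESHOLD = 0.5


@dataclass(frozen=True)
class TumorPrediction:
    """Per-sample probabilities and the tumor-level majority-vote call."""

    subject_id: str
    probabilities: np.ndarray  # p(y_hat = 1) per sample
    votes: np.ndarray  # binary vote per sample
    ties: np.ndarray  # samples with p exactly 0.5 (scored wrong in evaluation)
    vote_fraction: float
    predicted: int

    @property
    def n_samples(self) -> int:
        return len(self.probabilities)


def vote_from_probabilities(
    probs: np.ndarray, subject_id: str = "anon"
) -> TumorPrediction:
    """Apply the triplet-vote and tumor-vote rules to p(y = 1) values."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0:
        raise ValueError("expected a non-empty 1-D array of probabilities")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    votes = (probs > VOTE_THRESHOLD).astype(int)
    ties = probs == VOTE_THRESHOLD
    fraction = float(votes.mean())
    return TumorPrediction(
        subject_id=subject_id,
        probabilities=probs,
        votes=votes,
        ties=ties,
        vote_fraction=fraction,
        predicted=int(fraction > VOTE_THRESHOLD),
    )


def predict_tumor(
    model: CNNModel, roi: TumorROI, variant: str = "3s", normalize: bool = True
) -> TumorPrediction:
    """Majority-vote prediction for one tumor ROI.

    The 3S variant needs at least 3 slices (m-2 triplet votes); the 1S
    variant votes over all m slices.
    """
    embedded = embed_roi(roi, normalize=normalize)
    if variant == "3s":
        samples = build_triplets(embedded)
    elif variant == "1s":
        samples = build_singles(embedded)
    else:
        raise ValueError("variant must be '3s' or '1s'")
    probs = model.predict_proba(samples.astype(np.float32))[:, 1]
    return vote_from_probabilities(probs, subject_id=roi.subject_id)
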