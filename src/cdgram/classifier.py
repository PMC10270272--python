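"""Linear decision function mapping (SHI, THI) to a CDG value and call.

The shipped default is the frozen published linear boundary

    CDG value = -0.0556 * THI + 30.8131 * SHI - 2.7719

with decision rule: CDG value >= 0 is positive, < 0 negative.  The CDG value
is the (unnormalized) signed distance of a subject's (THI, SHI) point from
the boundary.  ``train_classifier`` reproduces the training *procedure* — a
linear-kernel support-vector machine on (THI, SHI) features — for research
use; it does not reproduce the frozen coefficients, whose training cohort is
not available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import TrainingError

PAPER_W_THI = -0.0556
PAPER_W_SHI = 30.8131
PAPER_BIAS = -2.7719


@dataclass
class CDGClassifier:
    """Linear decision function over (THI, SHI) with a fixed threshold."""

    w_thi: float = PAPER_W_THI
    w_shi: float = PAPER_W_SHI
    bias: float = PAPER_BIAS
    threshold: float = 0.0
    version: str = "paper-2023"

    def __post_init__(self):
        for v in (self.w_thi, self.w_shi, self.bias, self.threshold):
            if not math.isfinite(v):
                raise ValueError("classifier coefficients must be finite")

    @classmethod
    def paper_2023(cls) -> "CDGClassifier":
        """The frozen published coefficients (version tag ``paper-2023``)."""
        return cls()

    def cdg_value(self, idx) -> float:
        """w_thi * THI + w_shi * SHI + bias.

        ``idx`` is a :class:`~cdgram.heterogeneity.HeterogeneityIndices` or
        any object with ``shi``/``thi`` attributes, or a (shi, thi) pair.
        """
        if hasattr(idx, "shi"):
            shi, thi = idx.shi, idx.thi
        else:
            shi, thi = idx
        if not (math.isfinite(shi) and math.isfinite(thi)):
            raise ValueError("SHI and THI must be finite")
        return self.w_thi * thi + self.w_shi * shi + self.bias

    def classify(self, score: float) -> str:
        """``"positive"`` iff score >= threshold, else ``"negative"``."""
        if not math.isfinite(score):
            raise ValueError("score must be finite")
        return "positive" if score >= self.threshold else "negative"

    def __call__(self, idx):
        return self.classify(self.cdg_value(idx))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "w_thi": self.w_thi,
                    "w_shi": self.w_shi,
                    "bias": self.bias,
                    "threshold": self.threshold,
                    "version": self.version,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "CDGClassifier":
        with open(path) as fh:
            return cls(**json.load(fh))


def cdg_value(idx, clf: CDGClassifier | None = None) -> float:
    """Module-level convenience for :meth:`CDGClassifier.cdg_value`."""
    return (clf or CDGClassifier.paper_2023()).cdg_value(idx)


def classify(score: float, clf: CDGClassifier | None = None) -> str:
    """Module-level convenience for :meth:`CDGClassifier.classify`."""
    return (clf or CDGClassifier.paper_2023()).classify(score)


def train_classifier(indices, labels, c_reg: float = 1.0) -> CDGClassifier:
    """Fit a linear-kernel SVM on (THI, SHI) features.

    ``indices`` is a sequence of HeterogeneityIndices (or (shi, thi) pairs);
    ``labels`` are 0/1 with 1 = positive.  Deterministic for fixed inputs.
    """
    from sklearn.svm import SVC

    feats = []
    for idx in indices:
        if hasattr(idx, "shi"):
            feats.append((idx.thi, idx.shi))
        else:
            shi, thi = idx
            feats.append((thi, shi))
    x = np.asarray(feats, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires both classes present")
    svm = SVC(kernel="linear", C=c_reg)
    svm.fit(x, y)
    w = svm.coef_[0]
    return CDGClassifier(
        w_thi=float(w[0]),
        w_shi=float(w[1]),
        bias=float(svm.intercept_[0]),
        threshold=0.0,
        version="retrained",
    )
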