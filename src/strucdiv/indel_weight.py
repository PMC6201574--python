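"""Saturating indel-length -> flank-shift curve and gap-length weights.

The structural shift (RMSD, Å) of the regions flanking an indel grows with
the indel's length L and saturates: it is modelled as a first-order
exponential decay in increasing form,

    f(L) = c1 * exp(-L / c2) + c3,        c1 <= 0, c2 > 0,

so f rises from f(1) toward the asymptote c3. The weight of a gap of
length L is the fitted shift relative to a single-residue indel,
a_L = f(L) / f(1), giving a_1 = 1 exactly and a non-decreasing, bounded
weight sequence used by the length-weighted gap density (LSNG).

Fitting is constrained nonlinear least squares (scipy ``curve_fit`` with
the increasing-form bounds) with a deterministic, scale-aware start:
c3 from the largest per-length mean shift, c1 from the mean shift at the
smallest observed length, c2 = 2 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .alignment_model import IndelFlankSample
from .errors import FitError, IdentifiabilityError, InvalidModelError

_C2_MIN = 1e-8  # lower bound keeping the decay constant strictly positive


def _curve(L, c1, c2, c3):
    return c1 * np.exp(-np.asarray(L, dtype=float) / c2) + c3


@dataclass
class IndelWeightModel:
    """Fitted flank-shift curve ``f(L) = c1*exp(-L/c2) + c3``.

    ``c1`` (Å) is non-positive (increasing form), ``c2`` (residues) the
    decay constant, ``c3`` (Å) the large-L asymptote. ``param_se`` holds
    the standard errors of (c1, c2, c3) from the fit covariance when the
    model was fitted to data (None for models constructed directly).
    """

    c1: float
    c2: float
    c3: float
    fit_rss: float = 0.0
    n_samples: int = 0
    param_se: tuple[float, float, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.c1 > 1e-12:
            raise InvalidModelError(f"increasing form requires c1 <= 0, got {self.c1}")
        if self.c2 <= 0:
            raise InvalidModelError(f"decay constant c2 must be > 0, got {self.c2}")
        if self.fit_rss < 0:
            raise InvalidModelError("fit_rss must be >= 0")
        if predict_shift(self, 1) <= 0:
            raise InvalidModelError(
                f"f(1) = {predict_shift(self, 1):.4g} <= 0: weights undefined"
            )

    def weight(self, L: int) -> float:
        return weight(self, L)

    def to_yaml(self, path: str | Path) -> None:
        """Serialize the fitted parameters to a YAML config file."""
        payload = {
            "c1": float(self.c1),
            "c2": float(self.c2),
            "c3": float(self.c3),
            "fit_rss": float(self.fit_rss),
            "n_samples": int(self.n_samples),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IndelWeightModel":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            c1=float(data["c1"]),
            c2=float(data["c2"]),
            c3=float(data["c3"]),
            fit_rss=float(data.get("fit_rss", 0.0)),
            n_samples=int(data.get("n_samples", 0)),
        )


def fit_indel_curve(samples: list[IndelFlankSample]) -> IndelWeightModel:
    """Constrained least-squares fit of the saturating flank-shift curve.

    Requires samples at >= 3 distinct indel lengths (three parameters).
    The increasing form is enforced through the bounds c1 <= 0, c2 > 0.
    """
    if not samples:
        raise IdentifiabilityError("no flank samples provided")
    L = np.array([s.length for s in samples], dtype=float)
    y = np.array([s.rmsd for s in samples], dtype=float)
    order = np.lexsort((y, L))  # sample-order invariance
    L, y = L[order], y[order]
    lengths = np.unique(L)
    if lengths.size < 3:
        raise IdentifiabilityError(
            f"need samples at >= 3 distinct lengths to identify (c1, c2, c3); "
            f"got {lengths.size}"
        )
    mean_by_len = np.array([y[L == l].mean() for l in lengths])
    c3_0 = float(mean_by_len.max())
    c1_0 = min(float(mean_by_len[0] - c3_0), -1e-6)
    p0 = (c1_0, 2.0, c3_0)
    try:
        popt, pcov = curve_fit(
            _curve,
            L,
            y,
            p0=p0,
            bounds=([-np.inf, _C2_MIN, 0.0], [0.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"flank-curve fit did not converge: {exc}") from exc
    rss = float(np.sum((y - _curve(L, *popt)) ** 2))
    with np.errstate(invalid="ignore"):
        se = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
    return IndelWeightModel(
        c1=float(min(popt[0], 0.0)),
        c2=float(popt[1]),
        c3=float(popt[2]),
        fit_rss=rss,
        n_samples=len(samples),
        param_se=se,
    )


def predict_shift(model: IndelWeightModel, L: int) -> float:
    """Predicted flank RMSD (Å) for an indel of length L >= 1."""
    if L < 1:
        raise InvalidModelError(f"indel length must be >= 1, got {L}")
    return float(model.c1 * np.exp(-float(L) / model.c2) + model.c3)


def weight(model: IndelWeightModel, L: int) -> float:
    """Relative gap weight a_L = f(L)/f(1); a_1 = 1 exactly."""
    if L == 1:
        return 1.0
    f1 = predict_shift(model, 1)
    if f1 <= 0:
        raise InvalidModelError(f"f(1) = {f1:.4g} <= 0: weights undefined")
    return predict_shift(model, L) / f1


def weight_table(model: IndelWeightModel, l_max: int) -> list[tuple[int, float]]:
    """Weights for L = 1..l_max; non-decreasing, starting at exactly 1.0."""
    if l_max < 1:
        raise InvalidModelError(f"l_max must be >= 1, got {l_max}")
    return [(L, weight(model, L)) for L in range(1, l_max + 1)]


def unit_weights() -> IndelWeightModel:
    """A flat model (c1 = 0) whose weights are all exactly 1 (LSNG == SNG)."""
    return IndelWeightModel(c1=0.0, c2=1.0, c3=1.0)
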