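"""Apparent total ligand efficiency and the subtractive-average LE_δ.

The relative group contribution (RGC) idea: the efficiency of a drug-sized
molecule built from ``x`` fragments is estimated from its components' LE
values — either as a plain arithmetic mean,

    LE_T^app = (LE_1 + ... + LE_x) / x,

or, to respect differing fragment sizes, as a weighted root mean square,

    LE_T^app = sqrt( Σ LE_i² w_i / Σ w_i ),     w_i ∝ N_i by default.

Given a *target* apparent LE and ``a`` fragments whose LE is already known,
LE_δ is the single "ideal" value that each of the remaining ``x − a``
fragments would need so the whole molecule hits the target.  Arithmetically,

    LE_δ = (x·LE_T^app − Σ_known LE_j) / (x − a),

and in the weighted-RMS form (the unique expression consistent with the
averaging formula above — inserting x−a copies of (LE_δ, W_δ) reproduces the
target exactly):

    LE_δ = sqrt( (LE_T^app²·W_tot − Σ_known LE_j² w_j) / ((x−a)·W_δ) ),
    W_tot = Σ_known w_j + (x−a)·W_δ,

where W_δ is the common "ideal" weight assigned to the unknown fragments.
LE_δ shrinks as high-efficiency fragments become known — the quantitative
core of the fragment "rescue" effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .errors import (
    ConventionError,
    DeltaInfeasibleError,
    InvalidInputError,
    InvalidSlateError,
)
from .metrics import Fragment

#: Relative tolerance for the algebraic identities this module guarantees.
IDENTITY_RTOL: float = 1e-10


class AveragingMode(str, Enum):
    """How component-fragment efficiencies are pooled into an apparent total LE."""

    ARITHMETIC = "arithmetic"
    WRMS = "wrms"


@dataclass(frozen=True)
class ApparentLE:
    """An apparent total LE (kcal·mol⁻¹·HA⁻¹) tagged with its averaging mode."""

    value: float
    mode: AveragingMode

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise InvalidInputError(f"apparent LE must be finite, got {self.value}")

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class FragmentSlate:
    """The state of a partially solved combination: what is known, what is not.

    Parameters
    ----------
    x
        Total number of fragments in the molecule, ``x >= 1``.
    known
        ``(LE, weight)`` pairs for the ``a`` fragments with known efficiency.
        Weights are ignored in arithmetic mode but must still be positive.
    w_delta
        The common "ideal" weight W_δ given to each unknown fragment
        (weighted-RMS mode only).
    """

    x: int
    known: tuple[tuple[float, float], ...] = field(default=())
    w_delta: float = 1.0

    def __post_init__(self) -> None:
        if self.x < 1:
            raise InvalidSlateError(f"x must be >= 1, got {self.x}")
        object.__setattr__(self, "known", tuple((float(v), float(w)) for v, w in self.known))
        for v, w in self.known:
            if not (w > 0):
                raise InvalidSlateError(f"weights must be > 0, got {w}")
            if not math.isfinite(v):
                raise InvalidSlateError(f"known LE values must be finite, got {v}")
        if not (self.w_delta > 0):
            raise InvalidSlateError(f"w_delta must be > 0, got {self.w_delta}")

    @property
    def a(self) -> int:
        """Number of fragments with known LE."""
        return len(self.known)

    @property
    def n_unknown(self) -> int:
        return self.x - self.a

    def _require_delta_valid(self) -> None:
        if not (0 <= self.a < self.x):
            raise InvalidSlateError(
                f"LE_delta requires 0 <= a < x, got a={self.a}, x={self.x}"
            )


def _as_target(le_t_app: ApparentLE | float) -> float:
    return float(le_t_app)


def le_apparent_arithmetic(les: Sequence[float]) -> ApparentLE:
    """Arithmetic-mean apparent total LE; the single-fragment case is the identity."""
    if len(les) == 0:
        raise InvalidInputError("need at least one LE value")
    return ApparentLE(sum(les) / len(les), AveragingMode.ARITHMETIC)


def le_apparent_wrms(les: Sequence[float], weights: Sequence[float]) -> ApparentLE:
    """Weighted root-mean-square apparent total LE, sqrt(Σ LE_i² w_i / Σ w_i).

    All LE values must share one sign convention: mixing positive and negative
    inputs would silently destroy sign information under the square.
    """
    if len(les) == 0:
        raise InvalidInputError("need at least one LE value")
    if len(les) != len(weights):
        raise InvalidInputError(
            f"{len(les)} LE values but {len(weights)} weights"
        )
    for w in weights:
        if not (w > 0):
            raise InvalidInputError(f"weights must be > 0, got {w}")
    if any(v > 0 for v in les) and any(v < 0 for v in les):
        raise ConventionError(
            "mixed-sign LE values: convert to one convention before WRMS averaging"
        )
    num = sum(v * v * w for v, w in zip(les, weights))
    den = sum(weights)
    return ApparentLE(math.sqrt(num / den), AveragingMode.WRMS)


def le_delta_arithmetic(slate: FragmentSlate, le_t_app: ApparentLE | float) -> float:
    """Arithmetic LE_δ: the common LE the unknown fragments need to hit the target.

    Special cases guaranteed exactly: ``a = 0`` returns the target itself, and
    ``x − a = 1`` returns precisely the LE the single unknown fragment must have.
    """
    slate._require_delta_valid()
    target = _as_target(le_t_app)
    known_sum = sum(v for v, _ in slate.known)
    return (slate.x * target - known_sum) / slate.n_unknown


def le_delta_wrms(slate: FragmentSlate, le_t_app: ApparentLE | float) -> float:
    """Weighted-RMS LE_δ, the root of le_apparent_wrms(known + (x−a)×(LE_δ, W_δ)) = target.

    Raises
    ------
    DeltaInfeasibleError
        When the known fragments' squared-efficiency mass already exceeds what
        the target allows, so no real LE_δ solves the equality.  Callers doing
        cutoff screening should read this as "the target is already exceeded".
    """
    slate._require_delta_valid()
    target = _as_target(le_t_app)
    known_sq = sum(v * v * w for v, w in slate.known)
    w_known = sum(w for _, w in slate.known)
    w_tot = w_known + slate.n_unknown * slate.w_delta
    bracket = target * target * w_tot - known_sq
    if bracket < 0:
        # Tiny negatives from cancellation are a legitimate LE_delta of 0.
        if bracket >= -IDENTITY_RTOL * max(target * target * w_tot, known_sq, 1.0):
            bracket = 0.0
        else:
            raise DeltaInfeasibleError(
                f"no real LE_delta reaches apparent LE {target}: known fragments "
                f"overshoot by {-bracket} (kcal/mol/HA)^2 of weighted mass",
                bracket,
            )
    return math.sqrt(bracket / (slate.n_unknown * slate.w_delta))


def le_delta(
    slate: FragmentSlate, le_t_app: ApparentLE | float, mode: AveragingMode
) -> float:
    """Mode dispatcher for :func:`le_delta_arithmetic` / :func:`le_delta_wrms`."""
    if mode is AveragingMode.ARITHMETIC:
        return le_delta_arithmetic(slate, le_t_app)
    return le_delta_wrms(slate, le_t_app)


def default_weights(
    fragments: Iterable[Fragment], policy: str = "n_heavy"
) -> list[float]:
    """Per-fragment WRMS weights.

    The default policy weights each fragment by its heavy-atom count, so
    larger fragments pull the apparent LE harder; ``sqrt_n`` softens that and
    ``unit`` reduces WRMS to the unweighted RMS.
    """
    frags = list(fragments)
    if not frags:
        raise InvalidInputError("need at least one fragment")
    if policy == "n_heavy":
        return [float(f.n_heavy) for f in frags]
    if policy == "sqrt_n":
        return [math.sqrt(f.n_heavy) for f in frags]
    if policy == "unit":
        return [1.0 for _ in frags]
    raise InvalidInputError(f"unknown weight policy {policy!r}")
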