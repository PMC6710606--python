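"""Multi-pocket combinatorial fragment screening with rescue classification.

Classical fragment triage keeps a fragment only if its own LE clears a
cutoff.  Here the cutoff instead applies to the *apparent total LE* of a
full combination (one fragment per pocket), so a low-LE fragment survives —
is "rescued" — whenever high-LE partners in the other pockets lift the
combination over the bar.

The search is an exact branch-and-bound over pockets: a partial choice is
abandoned only when even the best remaining fragments cannot reach the
cutoff, so the accepted set equals exhaustive enumeration.  Acceptance of a
surviving leaf always re-evaluates the apparent LE with the same averaging
functions an exhaustive enumeration would use; pruning carries a small
safety slack so floating-point noise near the cutoff can never change the
result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import DeltaInfeasibleError, InvalidInputError, InvalidLibraryError
from .metrics import Fragment
from .rgc import (
    ApparentLE,
    AveragingMode,
    FragmentSlate,
    le_apparent_arithmetic,
    le_apparent_wrms,
    le_delta_arithmetic,
    le_delta_wrms,
)

#: Pruning safety slack: a branch is cut only when its optimistic completion
#: misses the cutoff by more than this, so boundary cases reach the exact test.
PRUNE_SLACK: float = 1e-9

#: Classification labels.
SELECTED = "selected"
RESCUED = "rescued"
REJECTED = "rejected"

INFEASIBLE: float = math.inf


@dataclass(frozen=True)
class PocketLibrary:
    """Fragments grouped by the binding pocket (position) they were screened against.

    ``pockets`` preserves insertion order, which defines the pocket order of
    every combination the screen reports.
    """

    pockets: dict[str, tuple[Fragment, ...]]
    target_id: str = ""

    def __post_init__(self) -> None:
        if len(self.pockets) < 1:
            raise InvalidLibraryError("a library needs at least one pocket")
        frozen: dict[str, tuple[Fragment, ...]] = {}
        for pocket_id, frags in self.pockets.items():
            frags = tuple(frags)
            seen: set[str] = set()
            for f in frags:
                if f.pocket_id != pocket_id:
                    raise InvalidLibraryError(
                        f"fragment {f.fragment_id!r} carries pocket_id {f.pocket_id!r} "
                        f"but sits in pocket {pocket_id!r}"
                    )
                if f.fragment_id in seen:
                    raise InvalidLibraryError(
                        f"duplicate fragment_id {f.fragment_id!r} in pocket {pocket_id!r}"
                    )
                seen.add(f.fragment_id)
            frozen[pocket_id] = frags
        object.__setattr__(self, "pockets", frozen)

    @classmethod
    def from_fragments(cls, fragments: Iterable[Fragment], target_id: str = "") -> "PocketLibrary":
        """Group a flat fragment list by pocket_id, preserving first-seen pocket order."""
        pockets: dict[str, list[Fragment]] = {}
        for f in fragments:
            pockets.setdefault(f.pocket_id, []).append(f)
        return cls({k: tuple(v) for k, v in pockets.items()}, target_id=target_id)

    @property
    def pocket_ids(self) -> list[str]:
        return list(self.pockets)

    @property
    def n_pockets(self) -> int:
        return len(self.pockets)

    def fragments(self) -> list[Fragment]:
        """All fragments, pocket by pocket."""
        return [f for frags in self.pockets.values() for f in frags]

    def __iter__(self):
        return iter(self.fragments())


@dataclass(frozen=True)
class ScreenConfig:
    """Screen settings.

    ``cutoff_le_t_app`` is the target apparent total LE (magnitude convention,
    kcal·mol⁻¹·HA⁻¹) a combination must reach.  ``tolerance`` relaxes the
    acceptance inequality to ``LE_T^app >= cutoff − tolerance``; it defaults
    to 0 (exact).  Non-binders (ΔG >= 0) are dropped unless
    ``allow_nonbinders`` is set, in which case they participate with an
    effective LE of 0.
    """

    cutoff_le_t_app: float
    mode: AveragingMode = AveragingMode.ARITHMETIC
    max_combinations_reported: int = 100_000
    allow_nonbinders: bool = False
    random_seed: int = 0
    tolerance: float = 0.0
    weight_policy: str = "n_heavy"

    def __post_init__(self) -> None:
        if not (self.cutoff_le_t_app >= 0):
            raise InvalidInputError(
                f"cutoff must be >= 0 in magnitude convention, got {self.cutoff_le_t_app}"
            )
        if self.tolerance < 0:
            raise InvalidInputError(f"tolerance must be >= 0, got {self.tolerance}")
        if isinstance(self.mode, str):
            object.__setattr__(self, "mode", AveragingMode(self.mode))

    @property
    def effective_cutoff(self) -> float:
        return self.cutoff_le_t_app - self.tolerance


@dataclass(frozen=True)
class Combination:
    """One fragment per pocket, with its apparent total LE and rescue annotation."""

    fragments: tuple[Fragment, ...]
    le_t_app: ApparentLE
    rescued_fragment_ids: tuple[str, ...]

    @property
    def fragment_keys(self) -> tuple[str, ...]:
        return tuple(f.key for f in self.fragments)


@dataclass(frozen=True)
class ScreenResult:
    """Accepted combinations plus a selected/rescued/rejected verdict per fragment.

    Classification keys are ``"pocket_id:fragment_id"``.  A fragment is
    *selected* when it clears the cutoff on its own and appears in at least
    one accepted combination, *rescued* when it appears despite an individual
    LE below the cutoff, and *rejected* when no accepted combination uses it.
    """

    accepted: tuple[Combination, ...]
    classification: dict[str, str]
    counts: dict[str, int]
    config: ScreenConfig
    n_evaluated: int = 0
    n_pruned_branches: int = 0
    n_total_combinations: int = 0


def screening_le(frag: Fragment) -> float:
    """Effective magnitude LE used by the screen: 0 for non-binders."""
    return max(0.0, -frag.delta_g) / frag.n_heavy


def _weight(frag: Fragment, policy: str) -> float:
    if policy == "n_heavy":
        return float(frag.n_heavy)
    if policy == "sqrt_n":
        return math.sqrt(frag.n_heavy)
    if policy == "unit":
        return 1.0
    raise InvalidInputError(f"unknown weight policy {policy!r}")


def _apparent(frags: Sequence[Fragment], config: ScreenConfig) -> ApparentLE:
    les = [screening_le(f) for f in frags]
    if config.mode is AveragingMode.ARITHMETIC:
        return le_apparent_arithmetic(les)
    return le_apparent_wrms(les, [_weight(f, config.weight_policy) for f in frags])


def _score(frag: Fragment, config: ScreenConfig) -> float:
    """Per-fragment acceptance margin; a combination passes iff Σ score >= 0.

    Arithmetic: mean >= c  ⇔  Σ (LE_i − c) >= 0.
    WRMS:       sqrt(Σ LE_i²w_i / Σ w_i) >= c  ⇔  Σ w_i(LE_i² − c²) >= 0.
    """
    le = screening_le(frag)
    c = config.effective_cutoff
    if config.mode is AveragingMode.ARITHMETIC:
        return le - c
    w = _weight(frag, config.weight_policy)
    return w * (le * le - c * c)


def _candidate_pockets(
    library: PocketLibrary, config: ScreenConfig
) -> dict[str, tuple[Fragment, ...]]:
    """Validate the library and drop non-binders unless allowed."""
    if any(len(frags) == 0 for frags in library.pockets.values()):
        empty = [p for p, frags in library.pockets.items() if not frags]
        raise InvalidLibraryError(f"empty pocket(s): {empty}")
    if not config.allow_nonbinders and not any(f.is_binder for f in library.fragments()):
        raise InvalidLibraryError(
            "library contains no binders (all fragments have ΔG >= 0); "
            "set allow_nonbinders=True to screen anyway"
        )
    if config.allow_nonbinders:
        return dict(library.pockets)
    return {p: tuple(f for f in frags if f.is_binder) for p, frags in library.pockets.items()}


def prune_bound(pocket: str, library: PocketLibrary) -> float:
    """Best (maximum) individual magnitude LE available in a pocket."""
    if pocket not in library.pockets:
        raise KeyError(pocket)
    frags = library.pockets[pocket]
    if not frags:
        raise InvalidLibraryError(f"pocket {pocket!r} is empty")
    return max(screening_le(f) for f in frags)


def screen(library: PocketLibrary, config: ScreenConfig) -> ScreenResult:
    """Enumerate all one-fragment-per-pocket combinations whose apparent LE clears the cutoff.

    Exact up to ordering: the accepted set is identical to brute-force
    enumeration.  Accepted combinations are sorted by apparent LE descending,
    then lexicographically by fragment ids; the list is truncated to
    ``config.max_combinations_reported`` (classification still reflects the
    full accepted set).
    """
    pockets = _candidate_pockets(library, config)
    pocket_ids = list(pockets)
    n = len(pocket_ids)
    cand = [pockets[p] for p in pocket_ids]
    total = math.prod(len(c) for c in cand)

    # Optimistic completion bound: best per-fragment score in each remaining pocket.
    best_scores = [max((_score(f, config) for f in c), default=-math.inf) for c in cand]
    suffix_best = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_best[i] = suffix_best[i + 1] + best_scores[i]

    accepted: list[Combination] = []
    stats = {"evaluated": 0, "pruned": 0}
    choice: list[Fragment] = []

    def dfs(i: int, score_sum: float) -> None:
        if score_sum + suffix_best[i] < -PRUNE_SLACK:
            stats["pruned"] += 1
            return
        if i == n:
            stats["evaluated"] += 1
            app = _apparent(choice, config)
            if app.value >= config.effective_cutoff:
                rescued = tuple(
                    f.key
                    for f in choice
                    if screening_le(f) < config.cutoff_le_t_app
                )
                accepted.append(Combination(tuple(choice), app, rescued))
            return
        for f in cand[i]:
            choice.append(f)
            dfs(i + 1, score_sum + _score(f, config))
            choice.pop()

    if all(cand_i for cand_i in cand):
        dfs(0, 0.0)

    accepted.sort(key=lambda c: (-c.le_t_app.value, c.fragment_keys))
    classification = classify_fragments(accepted, library, config)
    counts = {
        SELECTED: sum(1 for v in classification.values() if v == SELECTED),
        RESCUED: sum(1 for v in classification.values() if v == RESCUED),
        REJECTED: sum(1 for v in classification.values() if v == REJECTED),
        "accepted_combinations": len(accepted),
    }
    return ScreenResult(
        accepted=tuple(accepted[: config.max_combinations_reported]),
        classification=classification,
        counts=counts,
        config=config,
        n_evaluated=stats["evaluated"],
        n_pruned_branches=stats["pruned"],
        n_total_combinations=total,
    )


def classify_fragments(
    combinations: Sequence[Combination],
    library: PocketLibrary,
    config: ScreenConfig,
) -> dict[str, str]:
    """Partition every library fragment into selected / rescued / rejected."""
    in_accepted: set[str] = set()
    for combo in combinations:
        in_accepted.update(combo.fragment_keys)
    out: dict[str, str] = {}
    for f in library.fragments():
        if f.key not in in_accepted:
            out[f.key] = REJECTED
        elif screening_le(f) >= config.cutoff_le_t_app:
            out[f.key] = SELECTED
        else:
            out[f.key] = RESCUED
    return out


def classic_classification(library: PocketLibrary, config: ScreenConfig) -> dict[str, str]:
    """Classical per-fragment triage: selected iff the fragment's own LE clears the cutoff."""
    return {
        f.key: SELECTED if screening_le(f) >= config.cutoff_le_t_app else REJECTED
        for f in library.fragments()
    }


def required_le_for_remaining(
    partial: Sequence[Fragment],
    library: PocketLibrary,
    config: ScreenConfig,
) -> float:
    """The LE_δ fragments in the still-unfilled pockets must average to reach the cutoff.

    Returns 0.0 when the chosen fragments already fund the cutoff on their own
    ("any binder suffices"), and :data:`INFEASIBLE` (``math.inf``) when even
    the best fragments available in the unfilled pockets cannot reach it.
    """
    x = library.n_pockets
    chosen_pockets = [f.pocket_id for f in partial]
    if len(set(chosen_pockets)) != len(chosen_pockets):
        raise InvalidInputError("partial choice fills some pocket twice")
    unknown_pockets = [p for p in library.pocket_ids if p not in chosen_pockets]
    if not unknown_pockets:
        raise InvalidInputError("no unfilled pockets: partial choice is already complete")
    for p in chosen_pockets:
        if p not in library.pockets:
            raise KeyError(p)

    cutoff = config.effective_cutoff
    les = [screening_le(f) for f in partial]

    if config.mode is AveragingMode.ARITHMETIC:
        slate = FragmentSlate(x=x, known=tuple((le, 1.0) for le in les))
        required = max(0.0, le_delta_arithmetic(slate, cutoff))
        # Feasibility against the best each unfilled pocket can offer.
        optimistic = sum(les) + sum(
            max(screening_le(f) for f in library.pockets[p]) for p in unknown_pockets
        )
        feasible = optimistic >= x * cutoff - PRUNE_SLACK
    else:
        w_delta = _mean_candidate_weight(library, unknown_pockets, config)
        slate = FragmentSlate(
            x=x,
            known=tuple((le, _weight(f, config.weight_policy)) for le, f in zip(les, partial)),
            w_delta=w_delta,
        )
        try:
            required = le_delta_wrms(slate, cutoff)
        except DeltaInfeasibleError:
            required = 0.0  # the knowns already exceed the target mass
        optimistic_score = sum(_score(f, config) for f in partial) + sum(
            max(_score(f, config) for f in library.pockets[p]) for p in unknown_pockets
        )
        feasible = optimistic_score >= -PRUNE_SLACK

    return required if feasible else INFEASIBLE


def _mean_candidate_weight(
    library: PocketLibrary, unknown_pockets: Sequence[str], config: ScreenConfig
) -> float:
    """Default W_δ: mean weight of the candidate fragments in the unfilled pockets."""
    weights = [
        _weight(f, config.weight_policy)
        for p in unknown_pockets
        for f in library.pockets[p]
    ]
    return sum(weights) / len(weights)
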