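"""Shared test utilities: fragment builders and independent oracles.

The oracles here deliberately avoid the code paths they check: screening is
verified against plain exhaustive enumeration over ``itertools.product``,
and the closed-form weighted-RMS LE_δ against a bracketing root finder.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import brentq

from fragrescue import (
    AveragingMode,
    Fragment,
    PocketLibrary,
    ScreenConfig,
    le_apparent_arithmetic,
    le_apparent_wrms,
)


def make_fragment(le: float, n_heavy: int, pocket: str = "p1", fid: str = "f1") -> Fragment:
    """Fragment with magnitude LE ``le``: ΔG = −le·N."""
    return Fragment(fragment_id=fid, pocket_id=pocket, delta_g=-le * n_heavy, n_heavy=n_heavy)


def library_from_les(pocket_les: dict[str, list[float]], n_heavy: int = 10) -> PocketLibrary:
    """Library with given magnitude LEs per pocket, all fragments the same size."""
    pockets = {
        p: tuple(
            make_fragment(le, n_heavy, pocket=p, fid=f"{p}_f{i + 1}")
            for i, le in enumerate(les)
        )
        for p, les in pocket_les.items()
    }
    return PocketLibrary(pockets)


def random_library(rng: np.random.Generator, max_pockets: int = 4, max_frags: int = 6) -> PocketLibrary:
    """Random small library: uniform LEs in [0.05, 0.6], N in [5, 20]."""
    n_pockets = int(rng.integers(1, max_pockets + 1))
    pockets = {}
    for p in range(n_pockets):
        pocket_id = f"p{p + 1}"
        n_frags = int(rng.integers(1, max_frags + 1))
        frags = []
        for i in range(n_frags):
            le = float(rng.uniform(0.05, 0.6))
            n = int(rng.integers(5, 21))
            frags.append(make_fragment(le, n, pocket=pocket_id, fid=f"{pocket_id}_f{i + 1}"))
        pockets[pocket_id] = tuple(frags)
    return PocketLibrary(pockets)


def fragment_le(frag: Fragment) -> float:
    return max(0.0, -frag.delta_g) / frag.n_heavy


def brute_force_screen(library: PocketLibrary, config: ScreenConfig):
    """Exhaustive enumeration oracle.

    Returns (accepted keys as a set of fragment-key tuples, classification map)
    computed directly from the definitions, with no pruning.
    """
    if config.allow_nonbinders:
        candidates = [list(library.pockets[p]) for p in library.pocket_ids]
    else:
        candidates = [
            [f for f in library.pockets[p] if f.delta_g < 0] for p in library.pocket_ids
        ]
    cutoff = config.cutoff_le_t_app - config.tolerance
    accepted: set[tuple[str, ...]] = set()
    if all(candidates):
        for combo in itertools.product(*candidates):
            les = [fragment_le(f) for f in combo]
            if config.mode is AveragingMode.ARITHMETIC:
                app = le_apparent_arithmetic(les).value
            else:
                app = le_apparent_wrms(les, [float(f.n_heavy) for f in combo]).value
            if app >= cutoff:
                accepted.add(tuple(f.key for f in combo))
    in_accepted = {key for combo in accepted for key in combo}
    classification = {}
    for f in library.fragments():
        if f.key not in in_accepted:
            classification[f.key] = "rejected"
        elif fragment_le(f) >= config.cutoff_le_t_app:
            classification[f.key] = "selected"
        else:
            classification[f.key] = "rescued"
    return accepted, classification


def wrms_delta_by_rootfinding(
    known: list[tuple[float, float]], x: int, w_delta: float, target: float
) -> float:
    """Solve le_apparent_wrms(known + (x−a) copies of (v, w_delta)) = target for v >= 0."""
    n_unknown = x - len(known)
    les = [v for v, _ in known]
    ws = [w for _, w in known]

    def f(v: float) -> float:
        return (
            le_apparent_wrms(les + [v] * n_unknown, ws + [w_delta] * n_unknown).value
            - target
        )

    hi = target * math.sqrt((sum(ws) + n_unknown * w_delta) / (n_unknown * w_delta)) + 1.0
    if f(0.0) > 0:
        raise ValueError("target already exceeded by known fragments")
    return brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
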