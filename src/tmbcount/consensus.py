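"""Multi-caller consensus: the variant set all TMB counting runs on.

Independent somatic callers disagree substantially on borderline sites;
requiring agreement between callers is the standard way to trade a little
sensitivity for much higher precision.  After normalization (see
:mod:`tmbcount.variant_io`) agreement is exact-key equality on
``(contig, pos, ref, alt)``.

The default membership policy keeps a variant iff both Strelka2 and
Mutect2 report it; Manta membership is recorded but not required, since
Manta's role is to supply indel/SV candidates rather than final small
variants.  ``all`` and ``k-of-n:K`` policies are available for stricter or
looser ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

from .variant_io import (CALLER_ORDER, CallerVariantSet, NormalizedVariant,
                         classify_variant_type)

__all__ = ["ConsensusSet", "intersect_callers", "classify_variant_type",
           "DEFAULT_POLICY"]

DEFAULT_POLICY = "strelka2+mutect2"


@dataclass(frozen=True)
class ConsensusSet:
    """Variants surviving the caller-intersection policy, coordinate-sorted."""

    variants: tuple[NormalizedVariant, ...]
    policy: str
    input_tallies: Mapping[str, int]

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)


def _policy_rule(policy: str, present_callers: Sequence[str]) -> Callable[[frozenset], bool]:
    if policy == "all":
        required = frozenset(present_callers)
        return lambda callers: required <= callers
    if policy.startswith("k-of-n:"):
        try:
            k = int(policy.split(":", 1)[1])
        except ValueError:
            raise ValueError(f"malformed policy {policy!r}; expected k-of-n:<int>") from None
        if k < 1:
            raise ValueError(f"policy {policy!r}: k must be >= 1")
        return lambda callers: len(callers) >= k
    if "+" in policy:
        required = frozenset(policy.split("+"))
        unknown = required - set(CALLER_ORDER)
        if unknown:
            raise ValueError(f"policy {policy!r} names unknown callers: {sorted(unknown)}")
        missing = required - set(present_callers)
        if missing:
            raise ValueError(
                f"policy {policy!r} requires callers not provided: {sorted(missing)}")
        return lambda callers: required <= callers
    raise ValueError(f"unknown policy {policy!r}")


def intersect_callers(sets: Sequence[CallerVariantSet],
                      policy: str = DEFAULT_POLICY) -> ConsensusSet:
    """Intersect normalized caller sets under a membership policy.

    Annotation fields of a consensus variant are taken from the first
    caller, in fixed order (strelka2, mutect2, manta), that carries an
    ANN-derived impact; if none does, from the first caller that reported
    the variant.  This fixed precedence makes the output deterministic.
    """
    if not sets:
        raise ValueError("no caller sets given")
    names = [s.caller for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate caller names in input: {names}")
    if len(sets) < 2:
        raise ValueError("caller intersection needs at least two caller sets")

    rule = _policy_rule(policy, names)
    by_caller = {s.caller: {v.key: v for v in s.variants} for s in sets}
    ordered_callers = [c for c in CALLER_ORDER if c in by_caller]

    all_keys: set[tuple[str, int, str, str]] = set()
    for keyed in by_caller.values():
        all_keys |= keyed.keys()

    chosen: list[NormalizedVariant] = []
    for key in all_keys:
        supporting = frozenset(c for c in ordered_callers if key in by_caller[c])
        if not rule(supporting):
            continue
        donor = next((by_caller[c][key] for c in ordered_callers
                      if key in by_caller[c] and by_caller[c][key].impact is not None),
                     None)
        if donor is None:
            donor = next(by_caller[c][key] for c in ordered_callers if key in by_caller[c])
        chosen.append(replace(donor, callers=supporting))

    chosen.sort(key=lambda v: v.sort_key)
    tallies = {s.caller: len(s.variants) for s in sets}
    return ConsensusSet(variants=tuple(chosen), policy=policy, input_tallies=tallies)
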