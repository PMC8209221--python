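"""Structure specifications and pre-sampling simplification.

A tethered structure is an ordered chain of domains anchored at a tether
coordinate on the tile surface (the z = 0 plane, z increasing away from
the tile).  Exactly one domain is flagged as the reactive toehold — the
short single-stranded domain whose hybridization with its complement on
the partner structure initiates strand displacement.

Before sampling, a structure is simplified in two steps:

1. ``truncate_distal`` removes every domain farther from the tether than
   the reactive toehold; those domains cannot influence the toehold's
   position.
2. ``condense`` merges maximal runs of adjacent same-kind domains into
   single domains whose nucleotide counts are summed.  Duplex domains
   merge only when they are connected on both backbones (no intervening
   nick, i.e. ``nick_after`` is False on the upstream domain); the
   reactive toehold is never merged because both of its endpoints must
   be sampled to place the reactive point.

The *reactive point* of a sampled conformation is the midpoint of the
straight line between the two sampled endpoints of the reactive toehold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .biophysics import JointKind
from .errors import InvalidSpecError

__all__ = [
    "DomainSpec",
    "StructureSpec",
    "SampledStructure",
    "truncate_distal",
    "condense",
    "prepare",
    "reactive_point",
    "hairpin_wire_fixture",
    "STANDIN_FIXTURE_LENGTHS",
]


@dataclass(frozen=True)
class DomainSpec:
    """One DNA domain in a linear tethered structure.

    ``nick_after`` marks a backbone nick between this duplex domain and
    the next one; it controls both condensability (nicked neighbours are
    never merged) and is only meaningful for ds domains.
    """

    name: str
    kind: str  # "ss" | "ds"
    n_nt: int
    reactive: bool = False
    nick_after: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("ss", "ds"):
            raise InvalidSpecError(
                f"domain {self.name!r}: kind must be 'ss' or 'ds', got {self.kind!r}"
            )
        if isinstance(self.n_nt, bool) or not isinstance(self.n_nt, (int, np.integer)):
            raise InvalidSpecError(f"domain {self.name!r}: n_nt must be an integer")
        if self.n_nt < 1:
            raise InvalidSpecError(f"domain {self.name!r}: n_nt must be >= 1, got {self.n_nt}")
        object.__setattr__(self, "n_nt", int(self.n_nt))


@dataclass(frozen=True)
class StructureSpec:
    """Ordered chain of domains tethered to the tile surface."""

    name: str
    tether: tuple[float, float, float]
    domains: tuple[DomainSpec, ...]

    def __post_init__(self) -> None:
        tether = tuple(float(c) for c in self.tether)
        if len(tether) != 3:
            raise InvalidSpecError(f"structure {self.name!r}: tether must be a 3D coordinate")
        object.__setattr__(self, "tether", tether)
        domains = tuple(self.domains)
        object.__setattr__(self, "domains", domains)
        if not domains:
            raise InvalidSpecError(f"structure {self.name!r}: domain chain must be non-empty")
        n_reactive = sum(d.reactive for d in domains)
        if n_reactive != 1:
            raise InvalidSpecError(
                f"structure {self.name!r}: exactly one domain must be flagged reactive, "
                f"found {n_reactive}"
            )

    @property
    def reactive_index(self) -> int:
        for i, d in enumerate(self.domains):
            if d.reactive:
                return i
        raise AssertionError("unreachable: validated in __post_init__")

    def joints(self) -> tuple[JointKind, ...]:
        """Joint kind preceding each domain (tether first, then derived).

        Consecutive ds domains meet at a nick joint; any joint flanked by
        an ss domain is flexible (ss-ss or ss-ds).
        """
        kinds: list[JointKind] = [JointKind.TETHER]
        for prev, cur in zip(self.domains, self.domains[1:]):
            if prev.kind == "ds" and cur.kind == "ds":
                kinds.append(JointKind.DS_NICK)
            elif prev.kind == "ss" and cur.kind == "ss":
                kinds.append(JointKind.SS_SS)
            else:
                kinds.append(JointKind.SS_DS)
        return tuple(kinds)

    def total_nt(self) -> int:
        return sum(d.n_nt for d in self.domains)


@dataclass(frozen=True)
class SampledStructure:
    """One sampled conformation.

    ``joint_coords`` holds the tether followed by the distal end of each
    domain, in chain order, shape (n_domains + 1, 3).
    """

    joint_coords: np.ndarray
    reactive_point: np.ndarray


def truncate_distal(spec: StructureSpec) -> StructureSpec:
    """Drop every domain farther from the tether than the reactive toehold.

    Domains beyond the toehold cannot affect its position, so removing
    them leaves the colocation statistics unchanged while shortening the
    sampled chain.  Idempotent.
    """
    i = spec.reactive_index
    return replace(spec, domains=spec.domains[: i + 1])


def _mergeable(a: DomainSpec, b: DomainSpec) -> bool:
    if a.kind != b.kind or a.reactive or b.reactive:
        return False
    if a.kind == "ds" and a.nick_after:
        return False  # nicked duplexes flex at the nick; keep the joint
    return True


def condense(spec: StructureSpec) -> StructureSpec:
    """Merge maximal runs of adjacent same-kind domains.

    Nucleotide counts are summed, so rigid-rod and contour lengths are
    conserved.  The reactive toehold is never merged (its two endpoints
    define the reactive point), and duplex domains separated by a nick
    are not merged (the nick is a real joint).  Idempotent.
    """
    merged: list[DomainSpec] = []
    for d in spec.domains:
        if merged and _mergeable(merged[-1], d):
            prev = merged[-1]
            merged[-1] = DomainSpec(
                name=f"{prev.name}+{d.name}",
                kind=prev.kind,
                n_nt=prev.n_nt + d.n_nt,
                reactive=False,
                nick_after=d.nick_after,
            )
        else:
            merged.append(d)
    return replace(spec, domains=tuple(merged))


def prepare(spec: StructureSpec) -> StructureSpec:
    """Truncate past the reactive toehold, then condense. Idempotent."""
    return condense(truncate_distal(spec))


def reactive_point(joint_coords: np.ndarray, spec: StructureSpec) -> np.ndarray:
    """Midpoint of the sampled endpoints of the reactive toehold.

    ``joint_coords`` must contain the tether plus one coordinate per
    domain of ``spec`` (the distal end of each domain).
    """
    coords = np.asarray(joint_coords, dtype=float)
    if coords.shape != (len(spec.domains) + 1, 3):
        raise ValueError(
            f"joint_coords shape {coords.shape} does not match structure "
            f"{spec.name!r} with {len(spec.domains)} domains"
        )
    i = spec.reactive_index
    return 0.5 * (coords[i] + coords[i + 1])


#: Stand-in nucleotide counts for the two-hairpin signal-wire fixture.
#: The source experimental system does not print these domain lengths;
#: the values below are plausible placeholders of the right order (a
#: condensed duplex arm of toehold + recognition domain, and a short
#: ss tether spacer), NOT measured values.  Override to match a real
#: design.
STANDIN_FIXTURE_LENGTHS: dict[str, int] = {"d0": 16, "d1": 16, "spacer": 5}

#: Toehold length (nt) used throughout the fixture system.
FIXTURE_TOEHOLD_NT = 6


def hairpin_wire_fixture(
    which: str,
    inter_tether_distance: float = 10.88,
    lengths: dict[str, int] | None = None,
) -> StructureSpec:
    """Build one of the two structures of the tethered hairpin signal wire.

    ``H0`` is the opened upstream hairpin: two rigid duplex arms joined
    at a nick (condensed domains ``d0`` and ``d1``) ending in the exposed
    6-nt ss toehold ``x``, tethered at the origin.  ``H1`` is the
    downstream hairpin awaiting opening, reduced to an ss spacer plus the
    complementary 6-nt toehold ``x*``, tethered at
    (0, inter_tether_distance, 0).

    Domain lengths other than the toehold come from
    :data:`STANDIN_FIXTURE_LENGTHS` (documented stand-ins) unless
    overridden via ``lengths``.
    """
    if not inter_tether_distance > 0:
        raise InvalidSpecError(
            f"inter_tether_distance must be positive, got {inter_tether_distance!r}"
        )
    table = dict(STANDIN_FIXTURE_LENGTHS)
    if lengths:
        table.update(lengths)
    which = which.upper()
    if which == "H0":
        return StructureSpec(
            name="H0",
            tether=(0.0, 0.0, 0.0),
            domains=(
                DomainSpec("d0", "ds", table["d0"], nick_after=True),
                DomainSpec("d1", "ds", table["d1"]),
                DomainSpec("x", "ss", FIXTURE_TOEHOLD_NT, reactive=True),
            ),
        )
    if which == "H1":
        return StructureSpec(
            name="H1",
            tether=(0.0, float(inter_tether_distance), 0.0),
            domains=(
                DomainSpec("spacer", "ss", table["spacer"]),
                DomainSpec("x_star", "ss", FIXTURE_TOEHOLD_NT, reactive=True),
            ),
        )
    raise InvalidSpecError(f"unknown fixture {which!r}; expected 'H0' or 'H1'")
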