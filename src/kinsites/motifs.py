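"""Kinase consensus-motif matching and per-site category assignment.

A motif is a set of positional residue constraints around the
phospho-acceptor (offset 0).  In the bracket notation used in the mitotic
kinase literature:

* Cdk1:  ``[S/T-P]``                 — proline at +1;
* Ipl1 (Aurora B): ``[K/R-X-S/T-Y]`` — basic residue at −2, +1 anything
  except proline;
* Mps1:  ``[D/E/N/C-X-S/T-Y]``       — acidic/amide at −2, +1 anything
  except glutamate and proline;
* Cdc5 (Polo): no published regex in the source study; the shipped default
  (−2 ∈ {D,E}, +1 ∉ {E,P}) is a documented, non-authoritative stand-in and
  is fully configurable;
* Mps1 with −2 [S/T] phospho-priming — reported as a flag, not a category,
  because a phospho-Ser/Thr at −2 mimics the acidic residue the strict
  Mps1 motif requires.

Constraints are evaluated against an odd-length context window centered on
the phospho-residue; a ``-`` padding character beyond the protein terminus
fails an *allowed* constraint (the required residue cannot exist there) and
passes a *forbidden* one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import PAD

CATEGORY_OTHER = "Other"
#: category order used to break ties when one context matches several motifs
DEFAULT_PRECEDENCE: tuple[str, ...] = ("Mps1", "Ipl1", "Cdk1", "Cdc5")


@dataclass(frozen=True)
class Constraint:
    mode: str  # "allowed" | "forbidden"
    residues: frozenset[str]

    def __post_init__(self) -> None:
        if self.mode not in ("allowed", "forbidden"):
            raise ValueError(f"constraint mode must be allowed/forbidden, got {self.mode!r}")
        if not self.residues:
            raise ValueError("constraint residue set must be nonempty")


@dataclass(frozen=True)
class MotifPattern:
    """A kinase consensus motif as positional residue constraints.

    ``constraints`` maps a relative offset (never 0 — the center is governed
    by ``phospho_residues``) to a :class:`Constraint`.  ``role`` is
    ``"category"`` for motifs that compete for the single per-site category
    label and ``"flag"`` for variants reported alongside it.
    """

    name: str
    kinase: str
    phospho_residues: frozenset[str]
    constraints: Mapping[int, Constraint]
    role: str = "category"

    def __post_init__(self) -> None:
        if 0 in self.constraints:
            raise ValueError("offset 0 is governed by phospho_residues, not a constraint")
        if self.role not in ("category", "flag"):
            raise ValueError(f"role must be category/flag, got {self.role!r}")


@dataclass(frozen=True)
class SiteAssignment:
    """Motif calls for one site: all matches, the single category, and flags."""

    matched_motifs: tuple[str, ...]
    category: str
    mps1_primed: bool = False


def default_motifs() -> list[MotifPattern]:
    """The default motif set: Mps1, Ipl1, Cdk1, Cdc5 categories plus the
    Mps1 −2 [S/T] phospho-priming variant as a flag."""
    ST = frozenset("ST")
    return [
        MotifPattern(
            name="Mps1",
            kinase="Mps1",
            phospho_residues=ST,
            constraints={
                -2: Constraint("allowed", frozenset("DENC")),
                +1: Constraint("forbidden", frozenset("EP")),
            },
        ),
        MotifPattern(
            name="Ipl1",
            kinase="Aurora B (Ipl1)",
            phospho_residues=ST,
            constraints={
                -2: Constraint("allowed", frozenset("KR")),
                +1: Constraint("forbidden", frozenset("P")),
            },
        ),
        MotifPattern(
            name="Cdk1",
            kinase="Cdk1",
            phospho_residues=ST,
            constraints={+1: Constraint("allowed", frozenset("P"))},
        ),
        MotifPattern(
            name="Cdc5",
            kinase="Polo (Cdc5)",
            phospho_residues=ST,
            constraints={
                -2: Constraint("allowed", frozenset("DE")),
                +1: Constraint("forbidden", frozenset("EP")),
            },
        ),
        MotifPattern(
            name="Mps1_primed",
            kinase="Mps1",
            phospho_residues=ST,
            constraints={
                -2: Constraint("allowed", frozenset("ST")),
                +1: Constraint("forbidden", frozenset("EP")),
            },
            role="flag",
        ),
    ]


def match_site(context: str, motif: MotifPattern) -> bool:
    """True iff the center residue is an acceptor and every constraint holds.

    ``context`` must be an odd-length window centered on the phospho-residue
    and padded with ``-`` beyond the termini.
    """
    if len(context) % 2 == 0:
        raise ValueError(f"context must have odd length, got {len(context)}")
    center = len(context) // 2
    if context[center] not in motif.phospho_residues:
        return False
    for offset, constraint in motif.constraints.items():
        j = center + offset
        char = context[j] if 0 <= j < len(context) else PAD
        if constraint.mode == "allowed":
            if char not in constraint.residues:  # padding always fails
                return False
        else:  # forbidden: padding always passes
            if char in constraint.residues:
                return False
    return True


def assign_category(
    context: str,
    motifs: Sequence[MotifPattern] | None = None,
    precedence: Sequence[str] | None = None,
) -> SiteAssignment:
    """Evaluate every motif against ``context`` and pick one category label.

    ``matched_motifs`` lists every matching category-role motif in precedence
    order; the category is the highest-precedence match, or ``Other`` when
    none matches.  Flag-role motifs (phospho-priming) are evaluated
    independently and never set the category.
    """
    motifs = default_motifs() if motifs is None else motifs
    precedence = tuple(precedence) if precedence is not None else DEFAULT_PRECEDENCE
    by_name = {m.name: m for m in motifs}

    matched = [
        m.name for m in motifs if m.role == "category" and match_site(context, m)
    ]
    # order matches by precedence, any extras after, for a stable listing
    rank = {name: i for i, name in enumerate(precedence)}
    matched.sort(key=lambda n: (rank.get(n, len(rank)), n))
    category = next((n for n in precedence if n in matched), CATEGORY_OTHER)

    primed_motif = by_name.get("Mps1_primed")
    primed = bool(primed_motif) and match_site(context, primed_motif)
    return SiteAssignment(
        matched_motifs=tuple(matched), category=category, mps1_primed=primed
    )


def tally_categories(
    assignments: Iterable[SiteAssignment],
    categories: Sequence[str] | None = None,
) -> dict[str, int]:
    """Count assignments per category; counts always sum to the input length."""
    categories = tuple(categories) if categories is not None else (
        DEFAULT_PRECEDENCE + (CATEGORY_OTHER,)
    )
    tally = {c: 0 for c in categories}
    for a in assignments:
        tally[a.category] = tally.get(a.category, 0) + 1
    return tally


# --- configuration serialization --------------------------------------------

def motifs_to_config(motifs: Sequence[MotifPattern]) -> list[dict]:
    return [
        {
            "name": m.name,
            "kinase": m.kinase,
            "phospho_residues": sorted(m.phospho_residues),
            "constraints": [
                {
                    "offset": off,
                    "mode": c.mode,
                    "residues": sorted(c.residues),
                }
                for off, c in sorted(m.constraints.items())
            ],
            "role": m.role,
        }
        for m in motifs
    ]


def motifs_from_config(entries: Sequence[Mapping]) -> list[MotifPattern]:
    motifs = []
    for e in entries:
        motifs.append(
            MotifPattern(
                name=e["name"],
                kinase=e.get("kinase", e["name"]),
                phospho_residues=frozenset(e["phospho_residues"]),
                constraints={
                    int(c["offset"]): Constraint(c["mode"], frozenset(c["residues"]))
                    for c in e.get("constraints", [])
                },
                role=e.get("role", "category"),
            )
        )
    return motifs
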