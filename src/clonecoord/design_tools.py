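"""Golden Gate design validation and bench calculators.

Golden Gate assemblies join parts through the 4-base single-stranded
overhangs left by a Type IIS enzyme.  A part set forms a correct circular
plasmid only if the overhangs chain head-to-tail around the ring, every
junction overhang is unique, and no junction overhang is the reverse
complement of another (a reverse-complementary pair -- including a
palindromic overhang, which is its own reverse complement -- lets two
junctions ligate to each other and scrambles or linearizes the product).

The calculators cover the everyday bench arithmetic: length-normalized
concentration to molarity (1 ng/kb/uL = 1.623 nM, from the ~616 g/mol mean
molar mass of a double-stranded base pair), equimolar part pooling to a
target concentration, and premix scale-up with overage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "GGPart",
    "GGViolation",
    "MixPlan",
    "InfeasibleMixError",
    "NG_PER_KB_UL_TO_NM",
    "USER_2X_PREMIX",
    "reverse_complement",
    "validate_gg_design",
    "ng_per_kb_to_nM",
    "equimolar_mix_plan",
    "premix_plan",
]

#: nM of dsDNA per 1 ng/kb/uL of length-normalized concentration
NG_PER_KB_UL_TO_NM = 1.623

#: per-reaction composition of the standard USER 2x enzyme premix (uL);
#: 5 uL of this premix is added to each 10 uL assembly
USER_2X_PREMIX = {
    "HyClone water": 2.5,
    "10x Cutsmart buffer": 1.0,
    "DpnI": 0.75,
    "USER enzyme mix": 0.75,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GGPart:
    """One Golden Gate donor part with its enzyme-generated overhangs."""

    donor_id: str
    enzyme: str
    overhang_5: str
    overhang_3: str


@dataclass(frozen=True)
class GGViolation:
    rule: str  # "enzyme_mismatch" | "chain_break" | "duplicate_overhang" | "rc_collision"
    parts: tuple[str, ...]
    detail: str

    def __str__(self) -> str:
        return f"{self.rule} [{', '.join(self.parts)}]: {self.detail}"


def _check_overhang(part: GGPart, attr: str, length: int) -> Optional[GGViolation]:
    seq = getattr(part, attr)
    if len(seq) != length or any(b not in "ACGT" for b in seq):
        return GGViolation(
            "bad_overhang", (part.donor_id,),
            f"{attr}={seq!r} is not a {length}-base ACGT sequence",
        )
    return None


def validate_gg_design(
    parts: Sequence[GGPart], overhang_length: int = 4
) -> list[GGViolation]:
    """Validate an ordered part set against the Golden Gate assembly rules.

    Returns an empty list iff the design is valid: (a) each part's 3'
    overhang matches the next part's 5' overhang, cyclically closing the
    ring; (b) all junction overhangs are mutually distinct; (c) no junction
    overhang is the reverse complement of another junction overhang,
    itself included (palindromes are self-colliding).  Violations name the
    offending junction pair and rule.
    """
    if len(parts) < 2:
        raise ValueError("a Golden Gate design needs at least 2 parts")

    violations: list[GGViolation] = []

    enzymes = {p.enzyme for p in parts}
    if len(enzymes) > 1:
        violations.append(
            GGViolation("enzyme_mismatch", tuple(p.donor_id for p in parts),
                        f"multiple enzymes in one reaction: {sorted(enzymes)}")
        )

    for part in parts:
        for attr in ("overhang_5", "overhang_3"):
            bad = _check_overhang(part, attr, overhang_length)
            if bad:
                violations.append(bad)
    if violations:
        return violations

    n = len(parts)
    # (a) ring closure: 3' of part i must equal 5' of part i+1 (cyclic)
    for i, part in enumerate(parts):
        nxt = parts[(i + 1) % n]
        if part.overhang_3 != nxt.overhang_5:
            violations.append(
                GGViolation(
                    "chain_break", (part.donor_id, nxt.donor_id),
                    f"3' overhang {part.overhang_3} does not match next part's "
                    f"5' overhang {nxt.overhang_5}",
                )
            )

    # junction overhangs, one per adjacent pair, taken from the 3' side
    junctions = [(parts[i].donor_id, parts[(i + 1) % n].donor_id, parts[i].overhang_3)
                 for i in range(n)]

    # (b) mutual distinctness
    for i in range(n):
        for j in range(i + 1, n):
            if junctions[i][2] == junctions[j][2]:
                violations.append(
                    GGViolation(
                        "duplicate_overhang",
                        (junctions[i][0], junctions[i][1],
                         junctions[j][0], junctions[j][1]),
                        f"junction overhang {junctions[i][2]} used twice",
                    )
                )

    # (c) reverse-complement collisions, self included
    for i in range(n):
        for j in range(i, n):
            if junctions[i][2] == reverse_complement(junctions[j][2]):
                if i == j:
                    detail = f"palindromic junction overhang {junctions[i][2]}"
                else:
                    detail = (f"junction overhangs {junctions[i][2]} and "
                              f"{junctions[j][2]} are reverse complementary")
                violations.append(
                    GGViolation(
                        "rc_collision",
                        (junctions[i][0], junctions[i][1],
                         junctions[j][0], junctions[j][1]),
                        detail,
                    )
                )
    return violations


# ---------------------------------------------------------------------------
# Calculators
# ---------------------------------------------------------------------------


def ng_per_kb_to_nM(c_ng_per_kb_ul: float) -> float:
    """Convert a length-normalized dsDNA concentration (ng/kb/uL) to nM."""
    if c_ng_per_kb_ul < 0:
        raise ValueError("concentration must be >= 0")
    return c_ng_per_kb_ul * NG_PER_KB_UL_TO_NM


@dataclass
class MixPlan:
    """Pipetting plan for an equimolar part pool."""

    part_volumes_ul: list[float]
    water_volume_ul: float
    total_volume_ul: float
    per_part_nM: float
    per_part_ng_per_kb_ul: float
    premix_volume_ul: float = 0.0

    @property
    def volumes_sum_ul(self) -> float:
        return sum(self.part_volumes_ul) + self.water_volume_ul + self.premix_volume_ul


class InfeasibleMixError(ValueError):
    """Raised when part concentrations cannot reach the requested target.

    Because every required part volume scales proportionally with the final
    volume, feasibility depends only on the concentrations; the error
    therefore reports the limiting (most dilute, length-weighted) part and
    the maximum achievable target concentration.
    """

    def __init__(self, limiting_part: int, max_target: float):
        self.limiting_part = limiting_part
        self.max_achievable_target_ng_per_kb_ul = max_target
        super().__init__(
            f"part {limiting_part} is too dilute: maximum achievable target "
            f"concentration is {max_target:.3g} ng/kb/uL"
        )


def equimolar_mix_plan(
    parts: Sequence[tuple[float, float]],
    target_total_ng_per_kb_ul: float = 7.5,
    final_volume_ul: float = 5.0,
    per_part: bool = False,
) -> MixPlan:
    """Equimolar pooling plan for ``parts`` given as (length kb, conc ng/uL).

    Every part ends at the same molarity.  By default the *combined* molar
    concentration equals the target (each part contributes an equal share);
    with ``per_part=True`` each individual part is brought to the target
    instead.  Water fills to ``final_volume_ul``.
    """
    if not parts:
        raise ValueError("need at least one part")
    for i, (length_kb, conc) in enumerate(parts):
        if length_kb <= 0:
            raise ValueError(f"part {i}: length must be > 0")
        if conc <= 0:
            raise ValueError(f"part {i}: concentration must be > 0")
    if target_total_ng_per_kb_ul <= 0 or final_volume_ul <= 0:
        raise ValueError("target and final volume must be > 0")

    n = len(parts)
    share = target_total_ng_per_kb_ul if per_part else target_total_ng_per_kb_ul / n

    # part i needs share * length_i ng per uL of final mix
    fractions = [share * length_kb / conc for length_kb, conc in parts]
    if sum(fractions) > 1 + 1e-12:
        limiting = max(range(n), key=lambda i: fractions[i])
        max_target = target_total_ng_per_kb_ul / sum(fractions)
        raise InfeasibleMixError(limiting, max_target)

    volumes = [f * final_volume_ul for f in fractions]
    water = final_volume_ul - sum(volumes)
    return MixPlan(
        part_volumes_ul=volumes,
        water_volume_ul=water,
        total_volume_ul=final_volume_ul,
        per_part_nM=ng_per_kb_to_nM(share),
        per_part_ng_per_kb_ul=share,
    )


def premix_plan(
    recipe: dict[str, float], n_reactions: int, overage_fraction: float = 0.0
) -> dict[str, float]:
    """Scale a per-reaction premix recipe to ``n_reactions`` with overage.

    Returns the scaled component volumes plus a ``_per_reaction_ul`` entry
    giving the aliquot volume to add to each reaction (the sum of the
    unscaled recipe).
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if overage_fraction < 0:
        raise ValueError("overage_fraction must be >= 0")
    factor = n_reactions * (1 + overage_fraction)
    scaled = {name: vol * factor for name, vol in recipe.items()}
    scaled["_per_reaction_ul"] = sum(recipe.values())
    return scaled
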