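"""In-silico tryptic digestion and the theoretical peptide count N_k.

The protein inference model normalizes the number of experimentally observed
peptides n_k by the number of theoretical peptides N_k a protein could yield:
distinct tryptic fragments with at most ``max_missed_cleavages`` internal
cleavage sites whose neutral mass falls inside the mass window seen in the
identification report.  Trypsin cleaves C-terminal to K or R; by default the
K/R–P bond is not cleaved (the common proline rule), switchable off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from pyteomics import mass as _mass
from pyteomics import parser as _parser

from .report_io import PSMRecord, ValidationError, VALID_RESIDUES

_TRYPSIN_PROLINE = r"[KR](?!P)"
_TRYPSIN_PLAIN = r"[KR]"


@dataclass(frozen=True)
class DigestionSettings:
    """Digestion criteria and mass window for counting theoretical peptides.

    ``mass_min``/``mass_max`` are neutral peptide masses in Daltons; ``None``
    leaves that side unbounded (the pipeline normally fills them in from the
    report via :func:`infer_mass_window`).
    """

    max_missed_cleavages: int = 2
    mass_min: float | None = None
    mass_max: float | None = None
    mass_kind: str = "monoisotopic"
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValidationError("max_missed_cleavages must be >= 0")
        if self.mass_kind not in ("monoisotopic", "average"):
            raise ValidationError(f"unknown mass_kind {self.mass_kind!r}")
        if (
            self.mass_min is not None
            and self.mass_max is not None
            and not self.mass_min < self.mass_max
        ):
            raise ValidationError("mass_min must be < mass_max")
        if (self.mass_min is not None and self.mass_min <= 0) or (
            self.mass_max is not None and self.mass_max <= 0
        ):
            raise ValidationError("mass window bounds must be positive")


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - VALID_RESIDUES
    if not sequence or bad:
        raise ValidationError(
            f"invalid protein/peptide sequence: "
            + ("empty" if not sequence else f"illegal residues {sorted(bad)}")
        )


def tryptic_peptides(sequence: str, settings: DigestionSettings | None = None) -> set[str]:
    """Distinct tryptic fragments with <= max_missed_cleavages internal sites.

    No mass filter is applied here.  Cleavage is after K or R, skipping K/R–P
    bonds when the proline rule is on.
    """
    settings = settings or DigestionSettings()
    _check_sequence(sequence)
    rule = _TRYPSIN_PROLINE if settings.proline_rule else _TRYPSIN_PLAIN
    return set(
        _parser.cleave(sequence, rule, missed_cleavages=settings.max_missed_cleavages)
    )


def peptide_mass(sequence: str, mass_kind: str = "monoisotopic") -> float:
    """Neutral peptide mass in Daltons: sum of residue masses plus one water."""
    _check_sequence(sequence)
    if mass_kind == "monoisotopic":
        return _mass.fast_mass(sequence)
    if mass_kind == "average":
        return _mass.calculate_mass(sequence=sequence, average=True)
    raise ValidationError(f"unknown mass_kind {mass_kind!r}")


def count_theoretical_peptides(
    sequence: str, settings: DigestionSettings | None = None
) -> int:
    """N_k: distinct tryptic peptides of the protein inside the mass window."""
    settings = settings or DigestionSettings()
    lo = settings.mass_min if settings.mass_min is not None else 0.0
    hi = settings.mass_max if settings.mass_max is not None else math.inf
    count = 0
    for pep in tryptic_peptides(sequence, settings):
        if lo <= peptide_mass(pep, settings.mass_kind) <= hi:
            count += 1
    return count


def infer_mass_window(psms: Sequence[PSMRecord]) -> tuple[float, float]:
    """(M_min, M_max): the extremes of the reported peptide masses."""
    if not psms:
        raise ValidationError(
            "cannot infer mass window from an empty report; "
            "set digest.mass_min and digest.mass_max explicitly"
        )
    masses = [p.peptide_mass for p in psms]
    return min(masses), max(masses)
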