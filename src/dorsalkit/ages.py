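"""Developmental-age estimation and year-month age arithmetic.

Cognitive level in a heterogeneous clinical group is summarised as a
*developmental age* (DA): the median of the age-equivalents of the non-verbal
IQ subtests a child completed. Because IQ testing and the perceptual
assessment rarely happen on the same day, the DA measured at IQ time is
projected to the assessment date proportionally:

    DA_dorsal = (DA_IQ / CA_IQ) * CA_dorsal

where CA is chronological age. The projected DA is then used as the entry age
for the normative tables, except when the child is cognitively at (or above)
age level — performance IQ >= 100, or DA exceeding CA — in which case the
chronological age at assessment is used instead, so the entry age used for a
norm lookup never implies a reference group older than the child itself.

Ages are carried in months; the ``"4y3m"`` notation used by printed norm
tables round-trips through :func:`parse_ym` / :func:`format_ym`.
"""

from __future__ import annotations

import math
import re
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ValidationError

__all__ = [
    "AgeRecord",
    "DevelopmentalAge",
    "developmental_age",
    "parse_ym",
    "format_ym",
    "round_half_up",
]

_YM_RE = re.compile(r"^\s*(\d+)\s*y(?:\s*(\d+)\s*m)?\s*$")
_M_RE = re.compile(r"^\s*(\d+)\s*m\s*$")


def parse_ym(text: str) -> int:
    """Parse a year-month age string (``"4y3m"``, ``"5y"``, ``"51m"``) to months."""
    m = _YM_RE.match(text)
    if m:
        years, months = int(m.group(1)), int(m.group(2) or 0)
        if months >= 12:
            raise ValidationError(f"month part must be < 12 in {text!r}")
        return 12 * years + months
    m = _M_RE.match(text)
    if m:
        return int(m.group(1))
    raise ValidationError(f"cannot parse age {text!r}; expected e.g. '4y3m'")


def format_ym(months: float) -> str:
    """Format months as ``"XyYm"``. Fractional months are rounded half-up."""
    total = round_half_up(months)
    if total < 0:
        raise ValidationError(f"age must be non-negative, got {months}")
    return f"{total // 12}y{total % 12}m"


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (reporting convention)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class AgeRecord:
    """Ages needed for one patient's developmental-age estimate.

    Parameters
    ----------
    age_equivalents
        Age-equivalents (months) of the non-verbal IQ subtests.
    ca_iq
        Chronological age (months) at IQ testing.
    ca_dorsal
        Chronological age (months) at the dorsal-stream assessment.
    piq
        Performance IQ, if available.
    """

    age_equivalents: Sequence[float]
    ca_iq: float
    ca_dorsal: float
    piq: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.age_equivalents) == 0:
            raise ValidationError("at least one age-equivalent is required")
        if any(a <= 0 for a in self.age_equivalents):
            raise ValidationError("age-equivalents must be positive months")
        if self.ca_iq <= 0 or self.ca_dorsal <= 0:
            raise ValidationError("chronological ages must be positive months")


@dataclass(frozen=True)
class DevelopmentalAge:
    """Result of a developmental-age estimate (all ages in months)."""

    da_iq: float
    da_dorsal: float
    entry_age: float
    capped: bool  # True when CA replaced DA as the norm-table entry


def developmental_age(rec: AgeRecord) -> DevelopmentalAge:
    """Estimate developmental age and the norm-table entry age.

    DA_IQ is the median age-equivalent (even counts average the central
    pair); DA_dorsal projects it to the assessment date. The entry age is
    CA_dorsal when PIQ >= 100 or when DA_dorsal exceeds CA_dorsal, and
    DA_dorsal otherwise — so it never exceeds CA_dorsal by construction
    unless the child scores at age level, in which case it equals it.
    """
    da_iq = float(statistics.median(rec.age_equivalents))
    da_dorsal = (da_iq / rec.ca_iq) * rec.ca_dorsal
    capped = (rec.piq is not None and rec.piq >= 100) or da_dorsal > rec.ca_dorsal
    entry = float(rec.ca_dorsal) if capped else da_dorsal
    return DevelopmentalAge(da_iq=da_iq, da_dorsal=da_dorsal, entry_age=entry, capped=capped)
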