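"""Core domain types shared across the package.

A *site* is one candidate single-nucleotide substitution: chromosome,
1-based position, reference base and alternate base.  Every caller record,
feature vector and label in the pipeline is keyed by such a site, so two
calls at the same position with different alternate alleles are distinct
candidates (VCF semantics).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Optional

_BASES = frozenset("ACGT")


class Caller(str, Enum):
    MUTECT = "MUTECT"
    VCMM = "VCMM"
    AUX = "AUX"


class Platform(str, Enum):
    WGS = "WGS"
    WXS = "WXS"
    VALIDATION = "VALIDATION"


class Label(str, Enum):
    SOMATIC = "SOMATIC"
    NOT_SOMATIC = "NOT_SOMATIC"
    UNLABELED = "UNLABELED"


def _natural_chrom_key(chrom: str) -> tuple:
    """Sort key placing chr2 before chr10 (natural order)."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class GenomicSite:
    """One candidate SNV: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def sort_key(self) -> tuple:
        return (_natural_chrom_key(self.chrom), self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SourceId:
    """Identifies one caller running on one platform.

    ``aux_name`` labels auxiliary callers (e.g. consensus-labeling call
    sets) and must be present exactly when ``caller`` is AUX.
    """

    caller: Caller
    platform: Platform
    aux_name: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.caller is Caller.AUX) != (self.aux_name is not None):
            raise ValueError("aux_name must be present iff caller is AUX")


@dataclass
class CallerRecord:
    """One caller's evidence for one site on one platform.

    ``fields`` maps evidence names (read counts, qualities, judgement,
    failure reasons, ...) to values; absent evidence is simply absent from
    the map.  Only MuTect records carry a ``judgement``.
    """

    site: GenomicSite
    source: SourceId
    fields: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.fields.items():
            if key.endswith("_count") and isinstance(value, (int, float)) and value < 0:
                raise ValueError(f"negative read count {key}={value} at {self.site}")
        af = self.fields.get("allele_fraction")
        if af is not None and not (0.0 <= af <= 1.0):
            raise ValueError(f"allele fraction {af} outside [0,1]")
        has_judgement = "judgement" in self.fields
        if has_judgement != (self.source.caller is Caller.MUTECT):
            raise ValueError("judgement present iff caller is MUTECT")

    def get(self, name: str, default: Any = None) -> Any:
        return self.fields.get(name, default)
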