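"""Restriction enzyme definitions for reduced-representation library design.

An enzyme is its IUPAC recognition site plus the top-strand cut offset
(bases from the site start to the cut point, e.g. T^TAA has offset 1).
Only enzymes whose recognition site is palindromic are accepted for
digestion, because single-strand (forward-scan) cutting then coincides
with physical double-strand digestion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .genome import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_matches(code: str, base: str) -> bool:
    """True when genome ``base`` satisfies IUPAC ``code``. N in the genome
    matches nothing (avoids phantom cuts in assembly gaps)."""
    return base in IUPAC.get(code, "")


def site_pattern(site: str) -> re.Pattern[str]:
    """Compiled overlapping-occurrence regex for an IUPAC site."""
    body = "".join(f"[{IUPAC[c]}]" for c in site)
    return re.compile(f"(?={body})")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease, e.g. MseI = T^TAA."""

    name: str
    recognition_site: str
    cut_offset: int
    methylation_sensitive: bool = False
    _pattern: re.Pattern[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if len(site) < 4:
            raise ValueError(f"{self.name}: recognition site must be >= 4 bases, got {site!r}")
        bad = [c for c in site if c not in IUPAC]
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {bad} in site {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside site of length {len(site)}"
            )
        object.__setattr__(self, "recognition_site", site)
        object.__setattr__(self, "_pattern", site_pattern(site))

    @property
    def site_length(self) -> int:
        return len(self.recognition_site)

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition_site) == self.recognition_site

    @property
    def residual_prefix(self) -> str:
        """Bases a fragment (and thus a read) starts with after cutting:
        the part of the site downstream of the top-strand cut."""
        return self.recognition_site[self.cut_offset:]

    def expected_read_prefixes(self, bisulfite: bool = True) -> set[str]:
        """Literal prefixes expected at read starts.

        With ``bisulfite`` the C->T converted variant of the residual site
        is included (e.g. CviQI's TAC reads appear as TAC or TAT).
        """
        prefixes = {self.residual_prefix}
        if bisulfite:
            prefixes.add(self.residual_prefix.replace("C", "T"))
        return prefixes

    def cut_positions(self, seq: str) -> list[int]:
        """0-based top-strand cut coordinates in ``seq`` (overlapping site
        occurrences included); positions at 0 or len(seq) are dropped as
        they do not split the molecule."""
        seq = seq.upper()
        n = len(seq)
        cuts = []
        for m in self._pattern.finditer(seq):
            c = m.start() + self.cut_offset
            if 0 < c < n:
                cuts.append(c)
        return cuts


MseI = RestrictionEnzyme("MseI", "TTAA", 1)
CviQI = RestrictionEnzyme("CviQI", "GTAC", 1)
MspI = RestrictionEnzyme("MspI", "CCGG", 1)

BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {e.name: e for e in (MseI, CviQI, MspI)}


def get_enzyme(name_or_enzyme: str | RestrictionEnzyme) -> RestrictionEnzyme:
    if isinstance(name_or_enzyme, RestrictionEnzyme):
        return name_or_enzyme
    try:
        return BUILTIN_ENZYMES[name_or_enzyme]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name_or_enzyme!r}; built-ins: {sorted(BUILTIN_ENZYMES)}"
        ) from None


def load_enzyme_table(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Load enzymes from a plain-text TSV: name, site, cut_offset
    [, methylation_sensitive]. Lines starting with '#' are comments."""
    enzymes: dict[str, RestrictionEnzyme] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        name, site, offset = parts[0], parts[1], int(parts[2])
        sensitive = len(parts) > 3 and parts[3].strip().lower() in {"1", "true", "yes"}
        enzymes[name] = RestrictionEnzyme(name, site, offset, sensitive)
    return enzymes
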