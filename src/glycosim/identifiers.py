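"""Glycopeptide identifier parsing.

Identifications are labelled ``PEP{Hex;HexNAc;Fuc;Neu5Ac;Sulfate}``: a peptide
backbone tag followed by a brace block of five semicolon-separated monosaccharide
counts. Tokens without a brace block are accepted as peptide-only identifiers
with an all-zero composition (a warning is emitted), because some upstream
quantification exports omit the glycan when it could not be assigned.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

MONOSACCHARIDES: tuple[str, ...] = ("Hex", "HexNAc", "Fuc", "Neu5Ac", "Sulfate")

_TOKEN_RE = re.compile(r"^(?P<peptide>[^{}]+)\{(?P<comp>[^{}]*)\}$")


class GlycopeptideParseError(ValueError):
    """Raised when an identifier token has a malformed composition block."""


@dataclass(frozen=True)
class GlycopeptideId:
    """A peptide backbone plus an ordered glycan composition.

    The composition order is Hex, HexNAc, Fuc, Neu5Ac, Sulfate.
    """

    peptide: str
    composition: tuple[int, int, int, int, int]
    raw_label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.composition) != len(MONOSACCHARIDES):
            raise GlycopeptideParseError(
                f"composition must have {len(MONOSACCHARIDES)} counts, "
                f"got {len(self.composition)}"
            )
        if any(c < 0 for c in self.composition):
            raise GlycopeptideParseError("monosaccharide counts must be >= 0")

    @property
    def canonical(self) -> str:
        """Canonical ``PEP{a;b;c;d;e}`` form; parsing it round-trips."""
        return f"{self.peptide}{{{';'.join(str(c) for c in self.composition)}}}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def parse_glycopeptide_id(token: str) -> GlycopeptideId:
    """Parse an identifier token into a :class:`GlycopeptideId`.

    Parameters
    ----------
    token:
        Input label, e.g. ``"YnNT{7;6;0;1;0}"``.

    Raises
    ------
    GlycopeptideParseError
        If the brace block is present but malformed (wrong number of fields or
        non-integer counts).
    """
    token = token.strip()
    if not token:
        raise GlycopeptideParseError("empty glycopeptide identifier token")
    m = _TOKEN_RE.match(token)
    if m is None:
        if "{" in token or "}" in token:
            raise GlycopeptideParseError(f"malformed composition block in {token!r}")
        warnings.warn(
            f"identifier {token!r} has no composition block; "
            "treating as peptide-only with zero composition",
            stacklevel=2,
        )
        return GlycopeptideId(peptide=token, composition=(0, 0, 0, 0, 0), raw_label=token)
    fields = m.group("comp").split(";")
    if len(fields) != len(MONOSACCHARIDES):
        raise GlycopeptideParseError(
            f"composition block in {token!r} has {len(fields)} fields, "
            f"expected {len(MONOSACCHARIDES)}"
        )
    try:
        counts = tuple(int(f) for f in fields)
    except ValueError as exc:
        raise GlycopeptideParseError(
            f"non-integer monosaccharide count in {token!r}"
        ) from exc
    if any(c < 0 for c in counts):
        raise GlycopeptideParseError(f"negative monosaccharide count in {token!r}")
    return GlycopeptideId(peptide=m.group("peptide"), composition=counts, raw_label=token)
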