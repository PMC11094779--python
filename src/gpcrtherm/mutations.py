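"""Mutation naming: single substitutions and the text format used for them.

A mutation line reads ``<wt><position><mt> <chain>``, e.g. ``A123V A``:
wild-type single-letter code, author residue number, mutant single-letter
code, then the chain identifier separated by a space.
"""

from __future__ import annotations

import dataclasses
import re

from .errors import InvalidResidueError, MutationParseError
from .residues import STANDARD_AA1

_LINE_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])\s+(\S)$")


@dataclasses.dataclass(frozen=True)
class MutationSpec:
    """One single-point substitution on a specific chain."""

    chain: str
    position: int
    wt_aa: str
    mt_aa: str

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.mt_aa):
            if aa not in STANDARD_AA1:
                raise InvalidResidueError(f"{aa!r} is not a standard one-letter amino-acid code")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mt_aa} {self.chain}"


def parse_mutation_line(line: str, lineno: int | None = None) -> MutationSpec:
    """Parse one ``<wt><position><mt> <chain>`` line into a MutationSpec."""
    where = f"line {lineno}: " if lineno is not None else ""
    stripped = line.strip()
    if not stripped:
        raise MutationParseError(f"{where}empty mutation line")
    m = _LINE_RE.match(stripped)
    if m is None:
        if re.match(r"^[A-Za-z]\d+[A-Za-z]$", stripped):
            raise MutationParseError(
                f"{where}missing chain identifier in {stripped!r} "
                "(expected '<wt><position><mt> <chain>')"
            )
        raise MutationParseError(
            f"{where}malformed mutation {stripped!r} (expected '<wt><position><mt> <chain>')"
        )
    wt, pos, mt, chain = m.groups()
    try:
        return MutationSpec(chain=chain, position=int(pos), wt_aa=wt.upper(), mt_aa=mt.upper())
    except InvalidResidueError as exc:
        raise MutationParseError(f"{where}{exc}") from exc


def parse_mutation_file(path) -> list[MutationSpec]:
    """Parse a mutation-list file, one mutation per line; '#' starts a comment."""
    specs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if body:
                specs.append(parse_mutation_line(body, lineno=lineno))
    return specs
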