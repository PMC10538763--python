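"""Reading and writing pedigree genotype data in PLINK PED text format.

Alleles are kept in a mixed numeric encoding: STR alleles are exact decimal
rationals (``fractions.Fraction``; fractional repeat counts such as 9.3 are
legal and ``|9.3 - 10.3|`` is exactly 1), while alleles of non-STR markers
are mapped to distinct negative integers in order of first appearance in the
file.  The token ``0`` denotes a missing allele and is never a valid code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

__all__ = [
    "STR",
    "POLY",
    "MISSING_TOKEN",
    "PedParseError",
    "PedDataError",
    "MarkerPanel",
    "Individual",
    "Haplotype",
    "parse_ped",
    "write_ped",
    "read_marker_info",
    "build_dataset",
]

STR = "STR"
POLY = "POLY"
MISSING_TOKEN = "0"

#: allele of an STR marker (exact rational repeat count) or a non-STR code
Allele = Union[Fraction, int]

_SEX_CODES = {"1": "male", "2": "female"}
_SEX_TOKENS = {"male": "1", "female": "2"}
_STR_ALLELE_RE = re.compile(r"^\d+(\.\d+)?$")


class PedParseError(ValueError):
    """Malformed PED / marker-info file (structural problem, names the line)."""


class PedDataError(ValueError):
    """Well-formed file with inconsistent content (names individual/marker)."""


@dataclass
class MarkerPanel:
    """Marker names, order and per-marker type with allele encodings.

    ``allele_maps`` holds, for every non-STR marker index, the bijection from
    observed allele strings to negative integer codes.
    """

    names: tuple
    types: tuple
    allele_maps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.types = tuple(self.types)
        if len(self.names) != len(set(self.names)):
            raise PedDataError("marker names are not unique")
        if len(self.types) != len(self.names):
            raise PedDataError("marker types and names have different lengths")
        for t in self.types:
            if t not in (STR, POLY):
                raise PedDataError(f"unknown marker type {t!r}")
        self._decode_maps = {}
        for i, mapping in self.allele_maps.items():
            if self.types[i] != POLY:
                raise PedDataError(f"allele map given for STR marker {self.names[i]!r}")
            codes = list(mapping.values())
            if any(c >= 0 for c in codes) or len(codes) != len(set(codes)):
                raise PedDataError(
                    f"non-STR codes for marker {self.names[i]!r} must be distinct negative integers"
                )
            self._decode_maps[i] = {c: s for s, c in mapping.items()}

    @property
    def n_markers(self) -> int:
        return len(self.names)

    def is_str(self, i: int) -> bool:
        return self.types[i] == STR

    def encode_allele(self, i: int, token: str) -> Allele:
        """Encode one allele token for marker ``i`` (token must not be '0')."""
        if self.types[i] == STR:
            if not _STR_ALLELE_RE.match(token):
                raise PedDataError(
                    f"allele {token!r} is not a valid repeat count for STR marker {self.names[i]!r}"
                )
            return Fraction(token)
        try:
            return self.allele_maps[i][token]
        except KeyError:
            raise PedDataError(
                f"allele {token!r} not in the encoding of marker {self.names[i]!r}"
            ) from None

    def decode_allele(self, i: int, allele: Allele) -> str:
        """Inverse of :meth:`encode_allele` (used when writing PED rows)."""
        if self.types[i] == STR:
            return _format_repeat(allele)
        try:
            return self._decode_maps[i][allele]
        except KeyError:
            raise PedDataError(
                f"code {allele!r} unknown for marker {self.names[i]!r}"
            ) from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerPanel):
            return NotImplemented
        return (
            self.names == other.names
            and self.types == other.types
            and self.allele_maps == other.allele_maps
        )


def _format_repeat(allele) -> str:
    fr = Fraction(allele)
    if fr.denominator == 1:
        return str(fr.numerator)
    d = Decimal(fr.numerator) / Decimal(fr.denominator)
    return format(d.normalize(), "f")


@dataclass
class Haplotype:
    """Ordered vector of allele codes for one X chromosome; ``None`` = missing."""

    alleles: tuple

    def __post_init__(self) -> None:
        self.alleles = tuple(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    def __getitem__(self, i):
        return self.alleles[i]

    @property
    def missing_mask(self) -> tuple:
        return tuple(a is None for a in self.alleles)


@dataclass
class Individual:
    """One PED row.

    ``genotype`` has one entry per marker: a single allele code for males
    (hemizygous), a sorted pair for females, or ``None`` when missing.
    """

    family_id: str
    id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str
    genotype: list

    @property
    def is_male(self) -> bool:
        return self.sex == "male"

    @property
    def is_genotyped(self) -> bool:
        return any(g is not None for g in self.genotype)

    @property
    def fully_genotyped(self) -> bool:
        return all(g is not None for g in self.genotype)


def read_marker_info(path) -> tuple:
    """Read an optional marker-info file: tab-separated ``name`` / ``type`` columns.

    Returns ``(names, types_by_name)``; a leading header row is allowed.
    """
    names, types = [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise PedParseError(
                    f"{path}, line {lineno}: expected two columns (name, type)"
                )
            name, mtype = tokens
            if lineno == 1 and name.lower() == "name" and mtype.lower() == "type":
                continue
            mtype = mtype.upper()
            if mtype not in (STR, POLY):
                raise PedParseError(
                    f"{path}, line {lineno}: marker type must be STR or POLY, got {mtype!r}"
                )
            if name in types:
                raise PedParseError(f"{path}, line {lineno}: duplicated marker {name!r}")
            names.append(name)
            types[name] = mtype
    return names, types


def parse_ped(path, panel_hint=None) -> tuple:
    """Parse a PLINK PED file into ``(MarkerPanel, list_of_Individual)``.

    ``panel_hint`` optionally points to a marker-info file that overrides the
    inferred marker names and types.  Marker order is the PED column order.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if ncols is None:
                ncols = len(tokens)
                if ncols < 7:
                    raise PedParseError(
                        f"{path}, line {lineno}: expected at least 7 columns, found {ncols}"
                    )
                if (ncols - 6) % 2:
                    raise PedParseError(
                        f"{path}, line {lineno}: odd number of genotype columns ({ncols - 6})"
                    )
            elif len(tokens) != ncols:
                raise PedParseError(
                    f"{path}, line {lineno}: expected {ncols} columns, found {len(tokens)}"
                )
            rows.append((lineno, tokens))
    if not rows:
        raise PedParseError(f"{path}: empty PED file")
    marker_names = forced_types = None
    if panel_hint is not None:
        marker_names, forced_types = read_marker_info(panel_hint)
        if not marker_names:
            marker_names = None
    return build_dataset(rows, marker_names=marker_names, forced_types=forced_types)


def build_dataset(rows, marker_names=None, forced_types=None) -> tuple:
    """Encode validated token rows into a panel and individuals.

    ``rows`` is a list of ``(lineno, tokens)`` with a uniform column count.
    This is shared by :func:`parse_ped` and the simulator so both produce
    identical encodings for identical token streams.
    """
    ncols = len(rows[0][1])
    n = (ncols - 6) // 2
    names = list(marker_names) if marker_names is not None else [f"M{i + 1}" for i in range(n)]
    if len(names) != n:
        raise PedParseError(
            f"marker-info lists {len(names)} markers but the PED file has {n}"
        )
    forced_types = forced_types or {}

    types = []
    for i in range(n):
        forced = forced_types.get(names[i])
        if forced is not None:
            types.append(forced)
            continue
        mtype = STR
        for _, tokens in rows:
            for tok in tokens[6 + 2 * i : 8 + 2 * i]:
                if tok != MISSING_TOKEN and not _STR_ALLELE_RE.match(tok):
                    mtype = POLY
                    break
            if mtype == POLY:
                break
        types.append(mtype)

    # Non-STR codes: decreasing negative integers in order of first appearance
    # scanning the file row by row, markers left to right.
    allele_maps = {i: {} for i in range(n) if types[i] == POLY}
    for _, tokens in rows:
        for i in allele_maps:
            for tok in tokens[6 + 2 * i : 8 + 2 * i]:
                if tok != MISSING_TOKEN and tok not in allele_maps[i]:
                    allele_maps[i][tok] = -(len(allele_maps[i]) + 1)

    panel = MarkerPanel(tuple(names), tuple(types), allele_maps)

    individuals = []
    seen = set()
    for lineno, tokens in rows:
        fid, iid, father, mother, sex_code, _pheno = tokens[:6]
        if sex_code not in _SEX_CODES:
            raise PedDataError(
                f"line {lineno}: unknown sex code {sex_code!r} for individual {fid}:{iid}"
            )
        sex = _SEX_CODES[sex_code]
        if (fid, iid) in seen:
            raise PedDataError(f"duplicated individual ID {iid!r} in family {fid!r}")
        seen.add((fid, iid))
        genotype = []
        for i in range(n):
            a, b = tokens[6 + 2 * i], tokens[7 + 2 * i]
            if a == MISSING_TOKEN or b == MISSING_TOKEN:
                genotype.append(None)
                continue
            ea, eb = panel.encode_allele(i, a), panel.encode_allele(i, b)
            if sex == "male":
                if ea != eb:
                    raise PedDataError(
                        f"male {fid}:{iid} has two different alleles "
                        f"({a}, {b}) at marker {names[i]}"
                    )
                genotype.append(ea)
            else:
                genotype.append(tuple(sorted((ea, eb))))
        individuals.append(
            Individual(
                family_id=fid,
                id=iid,
                father_id=father if father != "0" else None,
                mother_id=mother if mother != "0" else None,
                sex=sex,
                genotype=genotype,
            )
        )
    return panel, individuals


def write_ped(individuals: Sequence[Individual], panel: MarkerPanel, path) -> None:
    """Write individuals as PED rows (males duplicated, missing as 0)."""
    lines = []
    for ind in individuals:
        if len(ind.genotype) != panel.n_markers:
            raise PedDataError(
                f"individual {ind.family_id}:{ind.id} has {len(ind.genotype)} markers, "
                f"panel has {panel.n_markers}"
            )
        tokens = [
            ind.family_id,
            ind.id,
            ind.father_id or "0",
            ind.mother_id or "0",
            _SEX_TOKENS[ind.sex],
            "0",
        ]
        for i, g in enumerate(ind.genotype):
            if g is None:
                tokens += [MISSING_TOKEN, MISSING_TOKEN]
            elif ind.is_male:
                tok = panel.decode_allele(i, g)
                tokens += [tok, tok]
            else:
                tokens += [panel.decode_allele(i, g[0]), panel.decode_allele(i, g[1])]
        lines.append(" ".join(tokens))
    Path(path).write_text("\n".join(lines) + "\n")
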