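"""Numbering-scheme definitions: positions, region boundary tables, templates.

Two schemes are supported, Kabat and IMGT, for heavy, kappa and lambda
variable domains.  Each (scheme, chain class) pair ships with a curated
*maximal* consensus template: an ordered list of columns covering every
position the scheme can assign, including the canonical Kabat insertion
columns (35A/B, 52A–C, 82A–C, 100A–E on the heavy chain; 27A–F and 95A/B on
light chains).  Queries are numbered by global alignment against these
columns (see :mod:`abgraft.numbering`).

The boundary tables and templates are versioned packaged data
(``data/numbering_schemes.json``); reports cite the version string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache, total_ordering
from importlib import resources
from typing import Optional

SCHEMES = ("kabat", "imgt")
CHAIN_CLASSES = ("heavy", "kappa", "lambda")
REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
CDR_REGIONS = ("CDR1", "CDR2", "CDR3")
FR_REGIONS = ("FR1", "FR2", "FR3", "FR4")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class SchemeError(ValueError):
    """Invalid scheme/chain-class/region request."""


def _load_raw() -> dict:
    with resources.files("abgraft.data").joinpath("numbering_schemes.json").open() as fh:
        return json.load(fh)


@total_ordering
@dataclass(frozen=True)
class SchemePosition:
    """A scheme position label: number plus optional insertion code.

    Insertion codes are single letters A–Z.  Under Kabat they occur at the
    canonical insertion points; under IMGT only CDR3 overflow past position
    111 carries codes.  Ordering is total within a chain: (number, code),
    with uncoded positions before coded ones of the same number.
    """

    scheme: str
    number: int
    insertion_code: Optional[str] = None

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise SchemeError(f"unknown scheme {self.scheme!r}")
        if self.number < 1:
            raise SchemeError(f"position number must be positive, got {self.number}")
        if self.insertion_code is not None and (
            len(self.insertion_code) != 1 or not "A" <= self.insertion_code <= "Z"
        ):
            raise SchemeError(f"bad insertion code {self.insertion_code!r}")

    @property
    def label(self) -> str:
        return f"{self.number}{self.insertion_code or ''}"

    def _key(self):
        return (self.number, self.insertion_code or "")

    def __lt__(self, other: "SchemePosition"):
        if self.scheme != other.scheme:
            raise SchemeError("cannot order positions from different schemes")
        return self._key() < other._key()

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class RegionSpan:
    """Inclusive start/end numbers of one region, plus insertion metadata."""

    name: str
    start: int
    end: int
    ins_point: Optional[int] = None
    ins_cols: int = 0

    def base_numbers(self) -> list[int]:
        return list(range(self.start, self.end + 1))

    def contains(self, pos: SchemePosition) -> bool:
        return self.start <= pos.number <= self.end


@dataclass(frozen=True)
class CdrBoundaryTable:
    """Per-region start/end spans for one scheme and chain class.

    ``spans`` is ordered FR1…FR4; regions are non-overlapping and each
    region's start ≤ end.
    """

    scheme: str
    chain_class: str
    spans: dict[str, RegionSpan]
    version: str

    def __post_init__(self):
        prev_end = 0
        for name in REGION_ORDER:
            span = self.spans[name]
            if span.start > span.end:
                raise SchemeError(f"{name}: start {span.start} > end {span.end}")
            if span.start <= prev_end:
                raise SchemeError(f"{name} overlaps preceding region")
            prev_end = span.end

    def region_of_number(self, number: int) -> str:
        for name, span in self.spans.items():
            if span.start <= number <= span.end:
                return name
        raise SchemeError(
            f"position {number} outside all {self.scheme}/{self.chain_class} regions"
        )

    def region_of(self, pos: SchemePosition) -> str:
        return self.region_of_number(pos.number)

    def cdr_numbers(self) -> set[int]:
        out: set[int] = set()
        for name in CDR_REGIONS:
            span = self.spans[name]
            out.update(range(span.start, span.end + 1))
        return out


@dataclass(frozen=True)
class TemplateColumn:
    position: SchemePosition
    region: str
    consensus_aa: str
    is_padding: bool = False  # canonical gap position (cheap to leave empty)


@dataclass(frozen=True)
class SchemeTemplate:
    """Maximal consensus template for one (scheme, chain class)."""

    scheme: str
    chain_class: str
    columns: tuple[TemplateColumn, ...]
    hard_anchors: dict[SchemePosition, str] = field(default_factory=dict)
    soft_anchors: dict[SchemePosition, str] = field(default_factory=dict)
    boundary: CdrBoundaryTable = None  # type: ignore[assignment]

    @property
    def consensus(self) -> str:
        return "".join(c.consensus_aa for c in self.columns)

    def column_index(self, pos: SchemePosition) -> int:
        for i, c in enumerate(self.columns):
            if c.position == pos:
                return i
        raise SchemeError(f"position {pos} not in template")


def _region_columns(
    scheme: str, span: RegionSpan, consensus: str, padding: frozenset[int] = frozenset()
) -> list[TemplateColumn]:
    labels: list[SchemePosition] = []
    for n in span.base_numbers():
        labels.append(SchemePosition(scheme, n))
        if span.ins_cols and n == span.ins_point:
            for k in range(span.ins_cols):
                labels.append(SchemePosition(scheme, n, chr(ord("A") + k)))
    if len(labels) != len(consensus):
        raise SchemeError(
            f"{scheme} {span.name}: consensus length {len(consensus)} != "
            f"{len(labels)} template columns"
        )
    return [
        TemplateColumn(
            p, span.name, aa,
            is_padding=(p.insertion_code is None and p.number in padding),
        )
        for p, aa in zip(labels, consensus)
    ]


@lru_cache(maxsize=None)
def get_template(scheme: str, chain_class: str) -> SchemeTemplate:
    """Load the curated template for a scheme and chain class."""
    if scheme not in SCHEMES:
        raise SchemeError(f"unknown scheme {scheme!r}")
    if chain_class not in CHAIN_CLASSES:
        raise SchemeError(f"unknown chain class {chain_class!r}")
    raw = _load_raw()
    entry = raw["schemes"][scheme][chain_class]
    version = raw["version"]
    spans: dict[str, RegionSpan] = {}
    columns: list[TemplateColumn] = []
    for reg in entry["regions"]:
        span = RegionSpan(
            reg["name"], reg["start"], reg["end"],
            reg.get("ins_point"), reg.get("ins_cols", 0),
        )
        spans[span.name] = span
        columns.extend(
            _region_columns(
                scheme, span, reg["consensus"],
                frozenset(reg.get("padding_cols", ())),
            )
        )
    boundary = CdrBoundaryTable(scheme, chain_class, spans, version)
    hard = {
        SchemePosition(scheme, int(k)): v for k, v in entry["hard_anchors"].items()
    }
    soft = {
        SchemePosition(scheme, int(k)): v for k, v in entry["soft_anchors"].items()
    }
    return SchemeTemplate(scheme, chain_class, tuple(columns), hard, soft, boundary)


def get_boundary_table(scheme: str, chain_class: str) -> CdrBoundaryTable:
    return get_template(scheme, chain_class).boundary


def j_consensus_fr4(chain_class: str) -> str:
    """Curated human J-segment FR4 consensus used when an acceptor lacks FR4."""
    raw = _load_raw()
    try:
        return raw["j_consensus_fr4"][chain_class]
    except KeyError:
        raise SchemeError(f"unknown chain class {chain_class!r}") from None


def cdr_labels_for_length(
    scheme: str, span: RegionSpan, length: int
) -> list[SchemePosition]:
    """Assign scheme labels to a CDR of a given observed length.

    IMGT fills symmetrically: ceil(L/2) positions from the span start and
    floor(L/2) from the span end, leaving the gap in the middle (N-terminal
    side gets the extra residue for odd lengths).  Overflow past the span is
    labelled with insertion codes at the span's insertion point (CDR3 only).

    Kabat anchors the tail after the canonical insertion point: positions
    after the insertion point are filled from the span end, the remainder
    from the span start, and overflow takes letter codes at the insertion
    point.
    """
    if length == 0:
        return []
    base = span.base_numbers()
    nbase = len(base)
    extra = max(0, length - nbase)
    if extra and span.ins_point is None:
        raise SchemeError(
            f"{span.name} length {length} exceeds the {scheme} span "
            f"{span.start}-{span.end} and the region admits no insertion codes"
        )
    if scheme == "imgt":
        if extra:
            left = [SchemePosition(scheme, n) for n in base if n <= span.ins_point]
            codes = [
                SchemePosition(scheme, span.ins_point, chr(ord("A") + k))
                for k in range(extra)
            ]
            right = [SchemePosition(scheme, n) for n in base if n > span.ins_point]
            return left + codes + right
        n_left = (length + 1) // 2
        n_right = length - n_left
        nums = base[:n_left] + (base[nbase - n_right:] if n_right else [])
        return [SchemePosition(scheme, n) for n in nums]
    # kabat
    p = span.ins_point if span.ins_point is not None else span.end
    left_base = [n for n in base if n <= p]
    right_base = [n for n in base if n > p]
    if extra:
        codes = [SchemePosition(scheme, p, chr(ord("A") + k)) for k in range(extra)]
        nums = [SchemePosition(scheme, n) for n in left_base]
        return nums + codes + [SchemePosition(scheme, n) for n in right_base]
    n_right = min(length, len(right_base))
    n_left = length - n_right
    nums = left_base[:n_left] + right_base[len(right_base) - n_right:]
    return [SchemePosition(scheme, n) for n in sorted(nums)]
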