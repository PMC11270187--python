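"""Kabat/IMGT numbering of antibody variable-domain sequences.

Numbering is done by global (Needleman–Wunsch) alignment of the query
against the curated per-scheme, per-chain-class consensus template of
:mod:`abgraft.schemes`, with position-specific gap penalties: gaps are
cheap inside CDR columns, expensive in framework columns, and effectively
forbidden at the conserved anchor cysteines.  After alignment, residues
falling in a CDR are re-labelled by the scheme's canonical fill rule
(symmetric middle-out gaps for IMGT, insertion-point-anchored codes for
Kabat), so that CDR length variation maps to the standard position sets.

The result is a :class:`NumberedChain`: an ordered list of
(position, residue) pairs partitioned into FR1…FR4 regions whose
concatenation reproduces the input sequence exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .schemes import (
    AA_ALPHABET,
    CDR_REGIONS,
    CHAIN_CLASSES,
    REGION_ORDER,
    CdrBoundaryTable,
    SchemePosition,
    SchemeTemplate,
    cdr_labels_for_length,
    get_template,
)

MIN_DOMAIN_LENGTH = 90
MAX_DOMAIN_LENGTH = 140


class UnnumberableError(ValueError):
    """The sequence cannot be aligned to any scheme template.

    ``anchor`` names the conserved anchor whose placement failed, when the
    failure is localized (e.g. ``"C23"``).
    """

    def __init__(self, message: str, anchor: Optional[str] = None):
        super().__init__(message)
        self.anchor = anchor


@dataclass(frozen=True)
class AntibodySequence:
    """A variable-domain amino-acid sequence.

    ``chain_class`` is one of ``heavy``, ``kappa``, ``lambda``; residues are
    uppercase one-letter codes from the 20 standard amino acids plus X.
    """

    id: str
    chain_class: str
    residues: str

    def __post_init__(self):
        if self.chain_class not in CHAIN_CLASSES:
            raise ValueError(f"unknown chain class {self.chain_class!r}")
        if not self.residues:
            raise ValueError("residues must be non-empty")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NumberedChain:
    """A sequence with scheme position labels and FR/CDR region assignment."""

    source: AntibodySequence
    scheme: str
    positions: tuple[tuple[SchemePosition, str], ...]
    region_of: dict[SchemePosition, str] = field(compare=False)
    table_version: str = ""

    def __post_init__(self):
        seq = "".join(aa for _, aa in self.positions)
        if seq != self.source.residues:
            raise ValueError(
                "positions do not reproduce the source sequence "
                f"({seq!r} vs {self.source.residues!r})"
            )

    @property
    def chain_class(self) -> str:
        return self.source.chain_class

    @property
    def sequence(self) -> str:
        return self.source.residues

    def position_map(self) -> dict[SchemePosition, str]:
        return dict(self.positions)

    def region_sequence(self, region: str) -> str:
        return "".join(aa for pos, aa in self.positions if self.region_of[pos] == region)

    def region_items(self, region: str) -> list[tuple[SchemePosition, str]]:
        return [(pos, aa) for pos, aa in self.positions if self.region_of[pos] == region]

    def framework_items(self) -> list[tuple[SchemePosition, str]]:
        return [
            (pos, aa)
            for pos, aa in self.positions
            if self.region_of[pos] not in CDR_REGIONS
        ]

    def regions_present(self) -> list[str]:
        seen = {self.region_of[pos] for pos, _ in self.positions}
        return [r for r in REGION_ORDER if r in seen]

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.source.id,
                "chain_class": self.chain_class,
                "scheme": self.scheme,
                "table_version": self.table_version,
                "positions": [
                    {
                        "number": pos.number,
                        "insertion_code": pos.insertion_code,
                        "region": self.region_of[pos],
                        "residue": aa,
                    }
                    for pos, aa in self.positions
                ],
            },
            indent=2,
        )


# -- alignment ---------------------------------------------------------------

_MATCH = 3.0
_MISMATCH_FR = -0.5
_MISMATCH_CDR = 0.5
_DEL_FR = 12.0
_DEL_CDR = 0.25
_DEL_PAD = 0.3
_DEL_ANCHOR = 1e5
_DEL_END = 0.05
_INS_CDR = 0.5
_INS_FR = 8.0


def _align(query: str, template: SchemeTemplate):
    """Global alignment; returns (col→query-index map, insertions).

    ``insertions`` is a list of (boundary j, query index): the query residue
    sits between template columns j-1 and j.
    """
    cols = template.columns
    n, m = len(cols), len(query)
    hard_numbers = {p.number for p in template.hard_anchors}
    is_cdr = [c.region in CDR_REGIONS for c in cols]
    del_cost = []
    for c in cols:
        if c.position.number in hard_numbers and c.position.insertion_code is None:
            del_cost.append(_DEL_ANCHOR)
        elif c.region in CDR_REGIONS or c.position.insertion_code is not None:
            # CDR columns and canonical insertion-code columns are cheap to skip
            del_cost.append(_DEL_CDR)
        elif c.is_padding:
            # canonical framework gap positions (e.g. IMGT 10, 73)
            del_cost.append(_DEL_PAD)
        else:
            del_cost.append(_DEL_FR)
    # insertion boundary j (0..n): cheap if adjacent to a CDR or insertion column
    def _cheap(jj: int) -> bool:
        return is_cdr[jj] or cols[jj].position.insertion_code is not None

    ins_cost = []
    for j in range(n + 1):
        adj = (j > 0 and _cheap(j - 1)) or (j < n and _cheap(j))
        ins_cost.append(_INS_CDR if adj else _INS_FR)

    NEG = float("-inf")
    score = [[NEG] * (n + 1) for _ in range(m + 1)]
    move = [[0] * (n + 1) for _ in range(m + 1)]  # 1=diag 2=up(ins) 3=left(del)
    score[0][0] = 0.0
    # semi-global: template columns skipped before the first / after the last
    # aligned query residue (leading/trailing truncation) are near-free
    for j in range(1, n + 1):
        score[0][j] = score[0][j - 1] - _DEL_END
        move[0][j] = 3
    for i in range(1, m + 1):
        score[i][0] = score[i - 1][0] - ins_cost[0]
        move[i][0] = 2
    for i in range(1, m + 1):
        qi = query[i - 1]
        row = score[i]
        prev = score[i - 1]
        mrow = move[i]
        last_row = i == m
        for j in range(1, n + 1):
            c = cols[j - 1]
            if qi == c.consensus_aa:
                sub = _MATCH
            elif qi == "X":
                sub = 0.0
            else:
                sub = _MISMATCH_CDR if is_cdr[j - 1] else _MISMATCH_FR
            best = prev[j - 1] + sub
            mv = 1
            up = prev[j] - ins_cost[j]
            if up > best:
                best, mv = up, 2
            left = row[j - 1] - (_DEL_END if last_row else del_cost[j - 1])
            if left > best:
                best, mv = left, 3
            row[j] = best
            mrow[j] = mv

    col_to_q: dict[int, int] = {}
    insertions: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 1:
            col_to_q[j - 1] = i - 1
            i, j = i - 1, j - 1
        elif mv == 2:
            insertions.append((j, i - 1))
            i -= 1
        else:
            j -= 1
    insertions.reverse()
    return col_to_q, insertions


def number_sequence(seq: AntibodySequence, scheme: str) -> NumberedChain:
    """Assign scheme positions and FR/CDR regions to a variable domain.

    Raises :class:`UnnumberableError` when the sequence is too short/long to
    be a variable domain or a conserved anchor cannot be placed.
    """
    if not MIN_DOMAIN_LENGTH <= len(seq.residues) <= MAX_DOMAIN_LENGTH:
        raise UnnumberableError(
            f"sequence {seq.id!r} length {len(seq.residues)} outside the "
            f"plausible variable-domain range "
            f"[{MIN_DOMAIN_LENGTH}, {MAX_DOMAIN_LENGTH}]; "
            "anchor C23 cannot be located",
            anchor="C23" if scheme == "imgt" else "C-first",
        )
    template = get_template(scheme, seq.chain_class)
    cols = template.columns
    col_to_q, insertions = _align(seq.residues, template)

    # hard anchors must be matched and be the expected residue
    for pos, aa in template.hard_anchors.items():
        j = template.column_index(pos)
        qi = col_to_q.get(j)
        if qi is None or seq.residues[qi] != aa:
            raise UnnumberableError(
                f"sequence {seq.id!r}: conserved anchor {aa}{pos.label} "
                f"({scheme}) could not be placed",
                anchor=f"{aa}{pos.label}",
            )

    # region of each query residue, in query order
    per_region: dict[str, list[int]] = {r: [] for r in REGION_ORDER}
    for j, qi in col_to_q.items():
        per_region[cols[j].region].append(qi)
    for j, qi in insertions:
        right = cols[j].region if j < len(cols) else None
        left = cols[j - 1].region if j > 0 else None
        if right in CDR_REGIONS:
            per_region[right].append(qi)
        elif left in CDR_REGIONS:
            per_region[left].append(qi)
        else:
            raise UnnumberableError(
                f"sequence {seq.id!r}: unalignable insertion in framework "
                f"region near column {cols[min(j, len(cols) - 1)].position.label}",
            )
    for r in per_region:
        per_region[r].sort()

    boundary = template.boundary
    positions: list[tuple[SchemePosition, str]] = []
    for region in REGION_ORDER:
        qis = per_region[region]
        if not qis:
            continue
        if region in CDR_REGIONS:
            labels = cdr_labels_for_length(scheme, boundary.spans[region], len(qis))
        else:
            labels = [cols[j].position for j in sorted(col_to_q) if cols[j].region == region]
        assert len(labels) == len(qis)
        positions.extend((lab, seq.residues[qi]) for lab, qi in zip(labels, qis))

    region_map = {pos: boundary.region_of(pos) for pos, _ in positions}
    return NumberedChain(
        source=seq,
        scheme=scheme,
        positions=tuple(positions),
        region_of=region_map,
        table_version=boundary.version,
    )


def extract_regions(chain: NumberedChain, table: CdrBoundaryTable) -> dict[str, str]:
    """Split a numbered chain into its seven region strings.

    The concatenation FR1+CDR1+…+FR4 reproduces the full sequence.  A region
    with no positions raises ``ValueError`` naming the region.
    """
    if chain.scheme != table.scheme:
        raise ValueError(
            f"chain numbered in {chain.scheme} but table is {table.scheme}"
        )
    out: dict[str, list[str]] = {r: [] for r in REGION_ORDER}
    for pos, aa in chain.positions:
        out[table.region_of(pos)].append(aa)
    for r in REGION_ORDER:
        if not out[r]:
            raise ValueError(f"region {r} absent")
    return {r: "".join(v) for r, v in out.items()}


def renumber(chain: NumberedChain, target_scheme: str) -> NumberedChain:
    """Re-label the same sequence under another scheme (round-trip stable)."""
    return number_sequence(chain.source, target_scheme)


def number_all(
    seqs: Iterable[AntibodySequence], scheme: str
) -> list[NumberedChain]:
    return [number_sequence(s, scheme) for s in seqs]
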