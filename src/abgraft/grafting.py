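"""CDR grafting: framework ranking, candidate panels, back-mutations.

The humanization workflow modelled here: rank human germline V genes by
framework identity to the parental chain, transplant the parental CDRs
(under a chosen CDR definition) onto the top acceptor frameworks, pair the
grafted heavy and light chains combinatorially into a candidate panel, and
restore selected framework residues to the parental amino acid
(back-mutation) with full provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .germline import GermlineEntry
from .numbering import (
    AntibodySequence,
    NumberedChain,
    number_sequence,
)
from .schemes import (
    CDR_REGIONS,
    FR_REGIONS,
    CdrBoundaryTable,
    SchemePosition,
    j_consensus_fr4,
)


class GraftError(ValueError):
    pass


@dataclass(frozen=True)
class FrameworkRanking:
    """Germline entries ordered by framework identity to a parental chain."""

    parental: NumberedChain
    entries: tuple[tuple[GermlineEntry, float, int], ...]

    def top(self, k: int) -> list[GermlineEntry]:
        return [e for e, _, _ in self.entries[:k]]


@dataclass(frozen=True)
class BackMutation:
    """Revert one framework position to the parental residue."""

    chain: str  # "heavy" | "light"
    position: SchemePosition
    from_aa: str
    to_aa: str

    def __str__(self) -> str:
        return f"{self.chain[0].upper()}:{self.from_aa}{self.position.label}{self.to_aa}"


@dataclass(frozen=True)
class GraftedChain:
    """A CDR-grafted chain with provenance."""

    chain: NumberedChain
    acceptor_gene: str
    parental_id: str
    cdr_scheme: str


@dataclass(frozen=True)
class GraftCandidate:
    """A humanized heavy/light pair with provenance.

    CDR positions (under ``cdr_scheme_used``) carry parental residues;
    framework positions carry acceptor residues except where a back-mutation
    is recorded in ``back_mutations``.
    """

    version_tag: str
    heavy: NumberedChain
    light: NumberedChain
    cdr_scheme_used: str
    acceptor_genes: tuple[str, str]
    back_mutations: tuple[BackMutation, ...] = field(default_factory=tuple)


def framework_identity(
    parental: NumberedChain, other: NumberedChain
) -> tuple[float, int]:
    """Fraction of shared framework positions with identical residues.

    The denominator counts framework positions present in both chains
    (gaps excluded); CDR positions are excluded entirely.
    """
    pmap = {p: aa for p, aa in parental.framework_items()}
    omap = {p: aa for p, aa in other.framework_items()}
    shared = set(pmap) & set(omap)
    if not shared:
        return 0.0, 0
    matches = sum(1 for p in shared if pmap[p] == omap[p])
    return matches / len(shared), len(shared)


def rank_frameworks(
    parental: NumberedChain,
    library: Sequence[GermlineEntry],
    top_k: Optional[int] = None,
) -> FrameworkRanking:
    """Rank germline entries by framework identity to the parental chain.

    Ties break by more aligned framework positions, then lexicographic gene
    name, so the ordering is deterministic.
    """
    if not library:
        raise GraftError("empty germline library")
    scored = []
    for entry in library:
        if entry.chain_class != parental.chain_class:
            continue
        numbered = number_sequence(entry.as_sequence(), parental.scheme)
        ident, aligned = framework_identity(parental, numbered)
        scored.append((entry, ident, aligned))
    if not scored:
        raise GraftError(
            f"no library entry matches chain class {parental.chain_class!r}"
        )
    scored.sort(key=lambda t: (-t[1], -t[2], t[0].gene_name))
    if top_k is not None:
        scored = scored[:top_k]
    return FrameworkRanking(parental=parental, entries=tuple(scored))


def graft(
    parental: NumberedChain,
    acceptor: GermlineEntry,
    table: CdrBoundaryTable,
) -> GraftedChain:
    """Transplant the parental CDRs onto the acceptor framework.

    Framework regions FR1–FR3 come from the acceptor; the CDRs (under the
    boundary table's scheme) come from the parental chain; FR4 comes from
    the acceptor when it has one (V genes normally do not) and otherwise
    from the curated human J-segment consensus for the chain class.
    """
    scheme = table.scheme
    if parental.scheme != scheme:
        parental = number_sequence(parental.source, scheme)
    acc = number_sequence(acceptor.as_sequence(), scheme)
    if acc.chain_class != parental.chain_class:
        raise GraftError(
            f"acceptor {acceptor.gene_name} chain class {acc.chain_class!r} "
            f"does not match parental {parental.chain_class!r}"
        )
    regions = {r: acc.region_sequence(r) for r in FR_REGIONS}
    for r in ("FR1", "FR2", "FR3"):
        if not regions[r]:
            raise GraftError(f"acceptor {acceptor.gene_name} missing region {r}")
    if not regions["FR4"]:
        regions["FR4"] = j_consensus_fr4(parental.chain_class)
    cdrs = {r: parental.region_sequence(r) for r in CDR_REGIONS}
    seq = (
        regions["FR1"] + cdrs["CDR1"] + regions["FR2"] + cdrs["CDR2"]
        + regions["FR3"] + cdrs["CDR3"] + regions["FR4"]
    )
    gid = f"{parental.source.id}@{acceptor.gene_name}"
    chain = number_sequence(
        AntibodySequence(gid, parental.chain_class, seq), scheme
    )
    for r in CDR_REGIONS:
        if chain.region_sequence(r) != cdrs[r]:
            raise GraftError(
                f"graft onto {acceptor.gene_name}: {r} was not preserved "
                "after renumbering the chimeric sequence"
            )
    return GraftedChain(
        chain=chain,
        acceptor_gene=acceptor.gene_name,
        parental_id=parental.source.id,
        cdr_scheme=scheme,
    )


def build_panel(
    heavy_variants: Sequence[GraftedChain],
    light_variants: Sequence[GraftedChain],
    tag_prefix: str = "V",
) -> list[GraftCandidate]:
    """Pair grafted chains combinatorially: |heavy| × |light| candidates.

    Version tags are deterministic, heavy-major: ``{prefix}H{i}L{j}`` with
    1-based indices in input order.
    """
    if not heavy_variants or not light_variants:
        raise GraftError("heavy and light variant lists must be non-empty")
    panel = []
    for i, hv in enumerate(heavy_variants, start=1):
        for j, lv in enumerate(light_variants, start=1):
            if hv.cdr_scheme != lv.cdr_scheme:
                raise GraftError("mixed CDR schemes within one panel")
            panel.append(
                GraftCandidate(
                    version_tag=f"{tag_prefix}H{i}L{j}",
                    heavy=hv.chain,
                    light=lv.chain,
                    cdr_scheme_used=hv.cdr_scheme,
                    acceptor_genes=(hv.acceptor_gene, lv.acceptor_gene),
                )
            )
    return panel


def _mutate_chain(chain: NumberedChain, mut: BackMutation) -> NumberedChain:
    pm = chain.position_map()
    if mut.position not in pm:
        raise GraftError(
            f"position {mut.position.label} absent from {chain.source.id}"
        )
    found = pm[mut.position]
    if found != mut.from_aa:
        raise GraftError(
            f"back-mutation at {chain.chain_class} {mut.position.label}: "
            f"expected {mut.from_aa}, found {found}"
        )
    positions = tuple(
        (p, mut.to_aa if p == mut.position else aa) for p, aa in chain.positions
    )
    seq = "".join(aa for _, aa in positions)
    src = AntibodySequence(chain.source.id, chain.chain_class, seq)
    # a point substitution does not move scheme labels; keep them
    return NumberedChain(
        source=src,
        scheme=chain.scheme,
        positions=positions,
        region_of=dict(chain.region_of),
        table_version=chain.table_version,
    )


def apply_back_mutations(
    candidate: GraftCandidate, mutations: Sequence[BackMutation]
) -> GraftCandidate:
    """Apply back-mutations to a candidate, appending to its ledger.

    Each mutation's ``from_aa`` must match the candidate's current residue
    at that position, else a :class:`GraftError` names position, expected
    and found residues.
    """
    heavy, light = candidate.heavy, candidate.light
    for mut in mutations:
        if mut.chain == "heavy":
            heavy = _mutate_chain(heavy, mut)
        elif mut.chain == "light":
            light = _mutate_chain(light, mut)
        else:
            raise GraftError(f"back-mutation chain must be heavy/light, got {mut.chain!r}")
    return replace(
        candidate,
        heavy=heavy,
        light=light,
        back_mutations=candidate.back_mutations + tuple(mutations),
    )
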