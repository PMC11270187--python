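"""Framework ranking, CDR grafting, panels and back-mutations."""

import pytest

from abgraft.germline import GermlineEntry
from abgraft.grafting import (
    BackMutation,
    GraftError,
    apply_back_mutations,
    build_panel,
    graft,
    rank_frameworks,
)
from abgraft.numbering import number_sequence
from abgraft.schemes import CDR_REGIONS, SchemePosition, get_boundary_table


class TestRankFrameworks:
    def test_self_framework_identity_is_one_and_ranked_first(
        self, parental_heavy_imgt, by_gene, human_heavy
    ):
        lib = human_heavy + [by_gene["IGHV2-9"]]
        ranking = rank_frameworks(parental_heavy_imgt, lib)
        top, ident, _ = ranking.entries[0]
        assert top.gene_name == "IGHV2-9"
        assert ident == pytest.approx(1.0)

    def test_hand_counted_toy_library_identities(self, parental_light_kabat):
        """Entries with 0, 2 and 8 planted framework mismatches rank in order."""
        base = parental_light_kabat
        fr_items = base.framework_items()
        seq = base.sequence

        def mutate(n_mut, tag):
            # mutate the first n_mut framework positions (skipping anchors C/W/F)
            chain = dict(base.positions)
            count = 0
            out = []
            for pos, aa in base.positions:
                if (
                    count < n_mut
                    and base.region_of[pos] not in CDR_REGIONS
                    and aa not in "CWF"
                    and 5 <= pos.number <= 20
                ):
                    out.append("A" if aa != "A" else "G")
                    count += 1
                else:
                    out.append(aa)
            assert count == n_mut
            return GermlineEntry(tag, "kappa", "".join(out), "toy")

        lib = [mutate(8, "g_eight"), mutate(0, "g_zero"), mutate(2, "g_two")]
        ranking = rank_frameworks(base, lib)
        names = [e.gene_name for e, _, _ in ranking.entries]
        assert names == ["g_zero", "g_two", "g_eight"]
        n_fr = len(fr_items)
        idents = [i for _, i, _ in ranking.entries]
        assert idents[0] == pytest.approx(1.0)
        assert idents[1] == pytest.approx((n_fr - 2) / n_fr)
        assert idents[2] == pytest.approx((n_fr - 8) / n_fr)

    def test_named_human_genes_are_top_hits(self, parental_heavy_imgt, library):
        """The three named human heavy genes lead the bundled heavy library."""
        lib = [e for e in library if e.gene_name != "IGHV2-9"]
        ranking = rank_frameworks(parental_heavy_imgt, lib, top_k=3)
        names = {e.gene_name for e, _, _ in ranking.entries}
        assert names == {"IGHV4-59", "IGHV2-26", "IGHV4-4"}

    def test_empty_library_rejected(self, parental_heavy_imgt):
        with pytest.raises(GraftError):
            rank_frameworks(parental_heavy_imgt, [])


class TestGraft:
    @pytest.mark.parametrize("scheme", ["imgt", "kabat"])
    def test_self_graft_reproduces_parental(self, scheme, parental_heavy, by_gene):
        parental = number_sequence(parental_heavy, scheme)
        table = get_boundary_table(scheme, "heavy")
        out = graft(parental, by_gene["IGHV2-9"], table)
        assert out.chain.sequence == parental.sequence

    def test_output_composition(self, parental_heavy_imgt, by_gene):
        table = get_boundary_table("imgt", "heavy")
        acc = by_gene["IGHV4-59"]
        out = graft(parental_heavy_imgt, acc, table).chain
        acc_numbered = number_sequence(acc.as_sequence(), "imgt")
        for r in CDR_REGIONS:
            assert out.region_sequence(r) == parental_heavy_imgt.region_sequence(r)
        for r in ("FR1", "FR2", "FR3"):
            assert out.region_sequence(r) == acc_numbered.region_sequence(r)
        exp_len = sum(len(acc_numbered.region_sequence(r)) for r in ("FR1", "FR2", "FR3"))
        exp_len += sum(len(parental_heavy_imgt.region_sequence(r)) for r in CDR_REGIONS)
        exp_len += len(out.region_sequence("FR4"))
        assert len(out.sequence) == exp_len

    def test_graft_idempotent_fixed_point(self, parental_heavy_imgt, by_gene):
        table = get_boundary_table("imgt", "heavy")
        acc = by_gene["IGHV2-26"]
        once = graft(parental_heavy_imgt, acc, table).chain
        twice = graft(once, acc, table).chain
        assert twice.sequence == once.sequence

    def test_kabat_vs_imgt_grafts_differ_inside_cdr_span_union(
        self, parental_heavy, by_gene
    ):
        """Scheme choice changes exactly the residues whose span class differs."""
        acc = by_gene["IGHV4-4"]
        gi = graft(
            number_sequence(parental_heavy, "imgt"), acc,
            get_boundary_table("imgt", "heavy"),
        ).chain
        gk = graft(
            number_sequence(parental_heavy, "kabat"), acc,
            get_boundary_table("kabat", "heavy"),
        ).chain
        assert gi.sequence != gk.sequence
        # index-align the Kabat graft's own regions with its IMGT labels
        gk_i = number_sequence(gk.source, "imgt")
        kabat_class = {
            pi: gk.region_of[pk] in CDR_REGIONS
            for (pi, _), (pk, _) in zip(gk_i.positions, gk.positions)
        }
        pos_i = dict(gi.positions)
        diffs = [
            pos for pos, aa in gk_i.positions
            if pos in pos_i and pos_i[pos] != aa
        ]
        assert diffs, "the two CDR definitions must disagree somewhere"
        for pos in diffs:
            imgt_is_cdr = gi.region_of[pos] in CDR_REGIONS
            # a residue can differ only where exactly one scheme calls it CDR
            assert imgt_is_cdr != kabat_class[pos]
        # both grafts carry the parental CDRs under their own definition
        for r in CDR_REGIONS:
            assert gi.region_sequence(r) == number_sequence(
                parental_heavy, "imgt"
            ).region_sequence(r)


class TestPanel:
    def _grafts(self, parental, genes, scheme, chain_class):
        table = get_boundary_table(scheme, chain_class)
        return [graft(parental, g, table) for g in genes]

    def test_three_by_three_gives_nine(
        self, parental_heavy_imgt, parental_light_imgt, human_heavy, human_kappa
    ):
        hs = self._grafts(parental_heavy_imgt, human_heavy, "imgt", "heavy")
        ls = self._grafts(parental_light_imgt, human_kappa, "imgt", "kappa")
        panel = build_panel(hs, ls, "V")
        assert len(panel) == 9
        assert [c.version_tag for c in panel[:4]] == ["VH1L1", "VH1L2", "VH1L3", "VH2L1"]

    def test_one_by_one_and_empty(self, parental_heavy_imgt, parental_light_imgt,
                                  human_heavy, human_kappa):
        hs = self._grafts(parental_heavy_imgt, human_heavy[:1], "imgt", "heavy")
        ls = self._grafts(parental_light_imgt, human_kappa[:1], "imgt", "kappa")
        assert len(build_panel(hs, ls)) == 1
        with pytest.raises(GraftError):
            build_panel(hs, [])

    def test_tags_stable_across_runs(
        self, parental_heavy_imgt, parental_light_imgt, human_heavy, human_kappa
    ):
        hs = self._grafts(parental_heavy_imgt, human_heavy, "imgt", "heavy")
        ls = self._grafts(parental_light_imgt, human_kappa, "imgt", "kappa")
        a = [c.version_tag for c in build_panel(hs, ls, "x")]
        b = [c.version_tag for c in build_panel(hs, ls, "x")]
        assert a == b


class TestBackMutations:
    @pytest.fixture()
    def v17_like(self, parental_heavy_kabat, parental_light_kabat, by_gene):
        th = get_boundary_table("kabat", "heavy")
        tl = get_boundary_table("kabat", "kappa")
        hs = [graft(parental_heavy_kabat, by_gene["IGHV2-26"], th)]
        ls = [graft(parental_light_kabat, by_gene["IGKV1-16"], tl)]
        return build_panel(hs, ls, "V17")[0]

    def test_s60k_g66r_yields_v21_like_with_ledger(self, v17_like, parental_light_kabat):
        muts = [
            BackMutation("light", SchemePosition("kabat", 60), "S", "K"),
            BackMutation("light", SchemePosition("kabat", 66), "G", "R"),
        ]
        v21 = apply_back_mutations(v17_like, muts)
        assert len(v21.back_mutations) == 2
        pm = v21.light.position_map()
        assert pm[SchemePosition("kabat", 60)] == "K"
        assert pm[SchemePosition("kabat", 66)] == "R"
        # the reverted residues now match the parental light chain
        ppm = parental_light_kabat.position_map()
        assert ppm[SchemePosition("kabat", 60)] == "K"
        assert ppm[SchemePosition("kabat", 66)] == "R"

    def test_empty_mutation_list_is_identity(self, v17_like):
        out = apply_back_mutations(v17_like, [])
        assert out.heavy.sequence == v17_like.heavy.sequence
        assert out.light.sequence == v17_like.light.sequence

    def test_from_aa_mismatch_names_position(self, v17_like):
        bad = BackMutation("light", SchemePosition("kabat", 60), "K", "S")
        with pytest.raises(GraftError, match="60"):
            apply_back_mutations(v17_like, [bad])

    def test_full_provenance_of_framework_residues(
        self, v17_like, parental_light_kabat, by_gene
    ):
        """Every framework residue traces to the acceptor or the ledger."""
        muts = [BackMutation("light", SchemePosition("kabat", 60), "S", "K")]
        v = apply_back_mutations(v17_like, muts)
        acc = number_sequence(by_gene["IGKV1-16"].as_sequence(), "kabat")
        acc_map = acc.position_map()
        ledger = {m.position: m.to_aa for m in v.back_mutations}
        for pos, aa in v.light.framework_items():
            if pos in ledger:
                assert aa == ledger[pos]
            elif pos in acc_map:
                assert aa == acc_map[pos]
            # FR4 positions come from the J consensus (acceptor lacks FR4)
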