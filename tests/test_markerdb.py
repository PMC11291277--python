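import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleozooms.markerdb import (
    MarkerDatabase,
    MarkerRecord,
    Taxonomy,
    TaxonNode,
    digest_sequence,
    lowest_consistent_taxon,
    peptide_mz,
    predict_markers,
)

HYDROXYLATION = 15.994915
DEAMIDATION = 0.984016


class TestDigest:
    def test_kp_exception(self):
        # manual rule application: K at 3 followed by P is not cleaved,
        # K at 7 is, R at 8 is; min_length 1 keeps everything
        assert digest_sequence("AAKPGGKRAA", 1, 0) == ["AAKPGGK", "R", "AA"]

    def test_no_cleavage_sites(self):
        assert digest_sequence("GGG", 1, 0) == ["GGG"]

    def test_missed_cleavage_enumeration(self):
        peptides = digest_sequence("AKR", 1, 1)
        assert "AKR" in peptides
        assert "AK" in peptides
        assert "R" in peptides

    def test_min_length_filter(self):
        assert digest_sequence("AAKGGGGGGR", 6, 0) == ["GGGGGGR"]

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            digest_sequence("AAZAA", 1, 0)

    def test_x_allowed(self):
        assert digest_sequence("AXAKGG", 1, 0) == ["AXAK", "GG"]


class TestPeptideMz:
    def test_p1105(self):
        # GVQGPPGPAGPR + 1 hydroxylation, the 1105 collagen marker
        assert peptide_mz("GVQGPPGPAGPR", 1, 0, 1) == pytest.approx(1105.57, abs=0.01)

    def test_p1105_deamidated(self):
        assert peptide_mz("GVQGPPGPAGPR", 1, 1, 1) == pytest.approx(1106.56, abs=0.01)

    def test_p1706(self):
        assert peptide_mz("DGEAGAQGPPGPAGPAGER", 1, 0, 1) == pytest.approx(
            1706.77, abs=0.01
        )

    def test_charge_division(self):
        mh = peptide_mz("GVQGPPGPAGPR", 1, 0, 1)
        mh2 = peptide_mz("GVQGPPGPAGPR", 1, 0, 2)
        assert mh2 == pytest.approx((mh + 1.007276) / 2, abs=1e-9)

    def test_too_many_hydroxylations(self):
        with pytest.raises(ValueError, match="hydroxylations"):
            peptide_mz("GGGR", 1, 0)

    def test_too_many_deamidations(self):
        with pytest.raises(ValueError, match="deamidations"):
            peptide_mz("GQGR", 0, 2)

    @given(
        n_hyd=st.integers(min_value=0, max_value=3),
        n_deam=st.integers(min_value=0, max_value=1),
    )
    def test_hydroxylation_additivity(self, n_hyd, n_deam):
        seq = "GPPGPPQGPR"  # 5 P, 1 Q
        lower = peptide_mz(seq, n_hyd, n_deam)
        upper = peptide_mz(seq, n_hyd + 1, n_deam)
        assert upper - lower == pytest.approx(HYDROXYLATION, abs=1e-12)

    def test_deamidation_shift_exact(self):
        seq = "GVQGPPGPAGPR"
        assert peptide_mz(seq, 1, 1) - peptide_mz(seq, 1, 0) == pytest.approx(
            DEAMIDATION, abs=1e-12
        )


class TestLowestConsistentTaxon:
    def test_nested_pair_returns_deepest(self, hominin_taxonomy):
        result = lowest_consistent_taxon(
            {hominin_taxonomy["Homininae"], hominin_taxonomy["Hominoidea"]}
        )
        assert result.name == "Homininae"

    def test_singleton(self, ungulate_taxonomy):
        assert (
            lowest_consistent_taxon({ungulate_taxonomy["Bos"]}).name == "Bos"
        )

    def test_conflicting_set_collapses_to_lca(self, ungulate_taxonomy):
        result = lowest_consistent_taxon(
            {
                ungulate_taxonomy["Caprinae"],
                ungulate_taxonomy["Bovidae"],
                ungulate_taxonomy["Cervidae"],
            }
        )
        assert result.name == "Artiodactyla"

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            lowest_consistent_taxon(set())

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_agrees_with_path_enumeration_oracle(self, data):
        # random taxonomy of up to 50 nodes, compare against brute force
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        ranks = ["species", "genus", "subfamily", "family", "superfamily", "order"]
        tax = Taxonomy(TaxonNode("root", "class"))
        nodes = [tax.root]
        n_nodes = int(rng.integers(2, 50))
        for i in range(n_nodes):
            parent = nodes[int(rng.integers(len(nodes)))]
            parent_level = ranks.index(parent.rank) if parent.rank in ranks else 6
            if parent_level == 0:
                continue
            rank = ranks[int(rng.integers(0, parent_level))]
            nodes.append(tax.add(f"n{i}", rank, parent.name))
        k = int(rng.integers(1, min(6, len(nodes)) + 1))
        chosen = [nodes[i] for i in rng.choice(len(nodes), size=k, replace=False)]

        # oracle: deepest node whose root path covers all chosen, else LCA by
        # explicit path intersection
        def path(n):
            out = []
            while n is not None:
                out.append(n)
                n = n.parent
            return out

        candidates = [
            c for c in chosen if all(x in path(c) for x in chosen)
        ]
        if candidates:
            ranks_all = ["species", "genus", "subfamily", "family", "superfamily", "order", "class"]
            expected = min(candidates, key=lambda n: ranks_all.index(n.rank))
        else:
            common = set(path(chosen[0]))
            for c in chosen[1:]:
                common &= set(path(c))
            ranks_all = ["species", "genus", "subfamily", "family", "superfamily", "order", "class"]
            expected = min(common, key=lambda n: ranks_all.index(n.rank))
        assert lowest_consistent_taxon(chosen) is expected


class TestPredictMarkers:
    def _two_taxon_setup(self):
        tax = Taxonomy(TaxonNode("Mammalia", "class"))
        tax.add("Fam", "family", "Mammalia")
        tax.add("SpX", "species", "Fam")
        tax.add("SpY", "species", "Fam")
        base = "GAVLSEDK" + "GGSSAAVVR" + "TTEEDDAAK"
        variant = "GAVLSEDK" + "GGSSAAVIR" + "TTEEDDAAK"  # one V->I inside pep 2
        return tax, {"SpX": base, "SpY": variant}

    def test_substitution_gives_species_marker(self):
        tax, seqs = self._two_taxon_setup()
        db = predict_markers(seqs, tax, hydroxylation_range=(0,))
        by_rank = {}
        for m in db:
            by_rank.setdefault(m.diagnostic_taxon.rank, []).append(m)
        species_seqs = {m.sequence for m in by_rank["species"]}
        assert "GGSSAAVVR" in species_seqs and "GGSSAAVIR" in species_seqs
        # unchanged peptides diagnostic at the two species' common parent
        assert {m.sequence for m in by_rank["family"]} == {"GAVLSEDK", "TTEEDDAAK"}

    def test_single_taxon_all_markers_at_that_taxon(self):
        tax = Taxonomy(TaxonNode("Mammalia", "class"))
        tax.add("Fam", "family", "Mammalia")
        tax.add("SpX", "species", "Fam")
        db = predict_markers(
            {"SpX": "GAVLSEDKGGSSAAVVR"}, tax, hydroxylation_range=(0,)
        )
        assert len(db) > 0
        assert all(m.diagnostic_taxon.name == "SpX" for m in db)

    def test_shared_derived_mass_tags_exclusive_ancestor(self):
        tax = Taxonomy(TaxonNode("Mammalia", "class"))
        tax.add("Fam1", "family", "Mammalia")
        tax.add("Fam2", "family", "Mammalia")
        tax.add("SpA", "species", "Fam1")
        tax.add("SpB", "species", "Fam1")
        tax.add("SpC", "species", "Fam2")
        shared = "GGSSAAVVR"
        derived = "GGSSAAVIR"
        seqs = {
            "SpA": "GAVLSEDK" + derived,
            "SpB": "GAVLSEDK" + derived,
            "SpC": "GAVLSEDK" + shared,
        }
        db = predict_markers(seqs, tax, hydroxylation_range=(0,))
        derived_markers = [m for m in db if m.sequence == derived]
        assert derived_markers and all(
            m.diagnostic_taxon.name == "Fam1" for m in derived_markers
        )

    def test_identical_sequences_only_root_level(self):
        tax = Taxonomy(TaxonNode("Mammalia", "class"))
        tax.add("Fam", "family", "Mammalia")
        tax.add("SpX", "species", "Fam")
        tax.add("SpY", "species", "Fam")
        tax.add("Fam2", "family", "Mammalia")
        tax.add("SpZ", "species", "Fam2")
        seq = "GAVLSEDKGGSSAAVVRTTEEDDAAK"
        db = predict_markers(
            {"SpX": seq, "SpY": seq, "SpZ": seq}, tax, hydroxylation_range=(0, 1)
        )
        assert len(db) > 0
        assert all(m.diagnostic_taxon is tax.root for m in db)

    def test_unknown_taxon_raises(self):
        tax = Taxonomy(TaxonNode("Mammalia", "class"))
        with pytest.raises(KeyError, match="Ghost"):
            predict_markers({"Ghost": "GAVLSEDK"}, tax)


class TestSerialization:
    def test_marker_db_round_trip(self, tmp_path, ungulate_taxonomy):
        tax = ungulate_taxonomy
        markers = [
            MarkerRecord("P1105", "GVQGPPGPAGPR", 1, 0,
                         peptide_mz("GVQGPPGPAGPR", 1, 0), tax["Caprinae"]),
            MarkerRecord("P1105", "GVQGPPGPAGPR", 1, 1,
                         peptide_mz("GVQGPPGPAGPR", 1, 1), tax["Caprinae"]),
            MarkerRecord("M2000", None, 0, 0, 2000.5, tax["Bos"], source="measured"),
        ]
        db = MarkerDatabase(tax, markers)
        path = tmp_path / "markers.tsv"
        db.to_tsv(path)
        again = MarkerDatabase.from_tsv(path, tax)
        assert len(again) == len(db)
        for a, b in zip(db, again):
            assert a.key == b.key
            assert a.sequence == b.sequence
            assert a.source == b.source
            assert a.mz_MH == pytest.approx(b.mz_MH, abs=5e-5)

    def test_taxonomy_round_trip(self, tmp_path, hominin_taxonomy):
        path = tmp_path / "taxonomy.tsv"
        hominin_taxonomy.to_tsv(path)
        again = Taxonomy.from_tsv(path)
        assert len(again) == len(hominin_taxonomy)
        assert again["Homo"].parent.name == "Homininae"
        assert again["Homo"].rank == "genus"

    def test_duplicate_marker_key_rejected(self, ungulate_taxonomy):
        record = MarkerRecord("P1105", "GVQGPPGPAGPR", 1, 0,
                              peptide_mz("GVQGPPGPAGPR", 1, 0),
                              ungulate_taxonomy["Caprinae"])
        with pytest.raises(ValueError, match="duplicate"):
            MarkerDatabase(ungulate_taxonomy, [record, record])

    def test_sequence_mass_consistency_enforced(self, ungulate_taxonomy):
        with pytest.raises(ValueError, match="inconsistent"):
            MarkerRecord("P1105", "GVQGPPGPAGPR", 1, 0, 1200.0,
                         ungulate_taxonomy["Caprinae"])


class TestTaxonomyInvariants:
    def test_rank_must_refine_parent(self):
        tax = Taxonomy(TaxonNode("root", "class"))
        tax.add("fam", "family", "root")
        with pytest.raises(ValueError, match="rank"):
            tax.add("bad", "order", "fam")

    def test_duplicate_names_rejected(self):
        tax = Taxonomy(TaxonNode("root", "class"))
        tax.add("a", "family", "root")
        with pytest.raises(ValueError, match="duplicate"):
            tax.add("a", "genus", "a")
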