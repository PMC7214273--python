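import numpy as np
import pytest

from meth3dlink import dmc_calling as dmc
from meth3dlink import pchic_integration as pchic
from meth3dlink.annotation import ProbeAnnotation, ProbeManifest
from meth3dlink.exceptions import ConfigError
from meth3dlink.io_formats import GenomicInterval, Interaction, InteractionSet


def make_interactions(other_ends, bait_genes=("G1",)):
    recs = []
    for i, (s, e) in enumerate(other_ends):
        recs.append(
            Interaction(
                bait=GenomicInterval("chrS", 100, 200),
                bait_genes=tuple(bait_genes),
                other_end=GenomicInterval("chrS", s, e),
                other_end_name=".",
                n_reads=10,
                score=8.0,
                id=f"int{i:06d}",
            )
        )
    return InteractionSet(recs)


def manifest_at(positions):
    return ProbeManifest(
        [ProbeAnnotation(pid, "chrS", pos, (), ()) for pid, pos in positions.items()]
    )


class TestMapCpgsToOtherEnds:
    def test_probe_inside_other_end_is_mapped(self):
        iset = make_interactions([(4000, 6000)])
        m = manifest_at({"p": 5000})
        assert pchic.map_cpgs_to_other_ends(["p"], iset, m) == {"p": ["int000000"]}

    def test_probe_outside_all_other_ends_unmapped(self):
        iset = make_interactions([(4000, 6000)])
        m = manifest_at({"p": 9000})
        assert pchic.map_cpgs_to_other_ends(["p"], iset, m) == {}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        other_ends = []
        for _ in range(150):
            s = int(rng.integers(0, 200_000))
            other_ends.append((s, s + int(rng.integers(500, 5000))))
        iset = make_interactions(other_ends)
        m = manifest_at({f"p{i}": int(rng.integers(1, 200_001)) for i in range(300)})
        mapping = pchic.map_cpgs_to_other_ends([f"p{i}" for i in range(300)], iset, m)
        oracle = {}
        for i in range(300):
            pid = f"p{i}"
            pos = m[pid].pos
            hits = sorted(
                rec.id
                for rec in iset
                if rec.other_end.start <= pos - 1 < rec.other_end.end
            )
            if hits:
                oracle[pid] = hits
        assert mapping == oracle

    def test_adding_interactions_never_unmaps(self):
        rng = np.random.default_rng(4)
        m = manifest_at({f"p{i}": int(rng.integers(1, 50_001)) for i in range(100)})
        ends = [
            (int(s), int(s) + 2000)
            for s in rng.integers(0, 48_000, size=30)
        ]
        small = make_interactions(ends[:15])
        large = make_interactions(ends)
        probes = [f"p{i}" for i in range(100)]
        mapped_small = set(pchic.map_cpgs_to_other_ends(probes, small, m))
        mapped_large = set(pchic.map_cpgs_to_other_ends(probes, large, m))
        assert mapped_small <= mapped_large

    def test_min_score_filter(self):
        iset = make_interactions([(4000, 6000)])
        m = manifest_at({"p": 5000})
        assert pchic.map_cpgs_to_other_ends(["p"], iset, m, min_score=9.0) == {}

    def test_bait_side_flag_admits_bait_probes(self):
        iset = make_interactions([(4000, 6000)])
        m = manifest_at({"p": 150})  # inside the bait [100, 200)
        assert pchic.map_cpgs_to_other_ends(["p"], iset, m) == {}
        assert pchic.map_cpgs_to_other_ends(
            ["p"], iset, m, include_bait_side=True
        ) == {"p": ["int000000"]}


class TestBuildDistalLinks:
    def test_planted_regulatory_signs_recovered(self, default_dataset):
        ds = default_dataset
        dmcs = dmc.call_dmcs(ds.beta)
        pass_ids = [r.probe_id for r in dmcs if r.passes]
        mapping = pchic.map_cpgs_to_other_ends(pass_ids, ds.interactions, ds.manifest)
        links = pchic.build_distal_links(
            mapping, ds.interactions, dmcs, ds.manifest, ds.beta, ds.expression
        )
        by_pair = {(l.probe_id, l.target_gene): l.reg_class for l in links}
        hits = total = 0
        for pid, gene_signs in ds.truth.distal_links.items():
            for gene, sign in gene_signs:
                total += 1
                hits += by_pair.get((pid, gene)) == sign
        assert hits / total >= 0.95

    def test_gene_class_split_partitions_target_genes(self, default_dataset):
        ds = default_dataset
        dmcs = dmc.call_dmcs(ds.beta)
        pass_ids = [r.probe_id for r in dmcs if r.passes]
        mapping = pchic.map_cpgs_to_other_ends(pass_ids, ds.interactions, ds.manifest)
        links = pchic.build_distal_links(
            mapping, ds.interactions, dmcs, ds.manifest, ds.beta, ds.expression
        )
        split = pchic.gene_class_split(links)
        assert split["enhancer_genes"] + split["silencer_genes"] == split["total_genes"]
        assert split["total_genes"] == len(
            {l.target_gene for l in pchic.correlated(links)}
        )

    def test_cpg_context_follows_manifest(self, default_dataset):
        ds = default_dataset
        dmcs = dmc.call_dmcs(ds.beta)
        pass_ids = [r.probe_id for r in dmcs if r.passes]
        mapping = pchic.map_cpgs_to_other_ends(pass_ids, ds.interactions, ds.manifest)
        links = pchic.build_distal_links(
            mapping, ds.interactions, dmcs, ds.manifest, ds.beta, ds.expression
        )
        for l in links:
            ann = ds.manifest[l.probe_id]
            if not ann.gene_symbols:
                assert l.cpg_context == "non_gene"
            else:
                assert l.cpg_context in {"gene_promoter", "gene_nonpromoter"}


class TestMultiplicityClasses:
    def _link(self, pid, gene, reg="enhancer"):
        return pchic.DistalLink(pid, "int000000", gene, -0.9, 0.001, reg, "non_gene")

    def test_single_gene_probe_is_unique(self):
        counts = pchic.multiplicity_classes([self._link("p", "CCR1")])
        assert counts == {"unique": 1, "dual": 0, "complex": 0}

    def test_two_gene_probe_is_dual(self):
        links = [self._link("p", "A"), self._link("p", "B")]
        assert pchic.multiplicity_classes(links)["dual"] == 1

    def test_planted_21_7_6_split(self):
        links = []
        for i in range(21):
            links.append(self._link(f"u{i}", f"G{i}"))
        for i in range(7):
            links += [self._link(f"d{i}", f"DA{i}"), self._link(f"d{i}", f"DB{i}")]
        for i in range(6):
            links += [self._link(f"c{i}", f"C{j}{i}") for j in range(3)]
        counts = pchic.multiplicity_classes(links)
        assert counts == {"unique": 21, "dual": 7, "complex": 6}
        assert sum(counts.values()) == 34

    def test_uncorrelated_links_do_not_count(self):
        links = [
            self._link("p", "A"),
            pchic.DistalLink("p", "i", "B", 0.1, 0.9, "uncorrelated", "non_gene"),
        ]
        assert pchic.multiplicity_classes(links) == {
            "unique": 1, "dual": 0, "complex": 0,
        }


class TestCtcfOverlap:
    def test_probe_inside_supplied_interval(self):
        m = manifest_at({"p": 1000})
        sites = [GenomicInterval("chrS", 995, 1005, "CTCF")]
        assert pchic.ctcf_overlap(["p"], m, motif_sites=sites) == {"p"}

    def test_empty_track_gives_empty_subset(self):
        m = manifest_at({"p": 1000})
        assert pchic.ctcf_overlap(["p"], m, motif_sites=[]) == set()

    def test_no_track_or_sequence_is_config_error(self):
        m = manifest_at({"p": 1000})
        with pytest.raises(ConfigError):
            pchic.ctcf_overlap(["p"], m)

    def test_iupac_scan_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(12)
        pattern = "CCGCGNGGNGGCAG"
        bases = "ACGT"
        seq = list(rng.choice(list(bases), size=200))
        planted_fwd = "CCGCGTGGAGGCAG"
        planted_rev = "CTGCCTCCTCGCGG"  # reverse complement of a match
        seq[20:34] = planted_fwd
        seq[120:134] = planted_rev
        seq = "".join(seq)

        iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT",
                 "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "R": "Y",
                "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K"}
        rc_pattern = "".join(comp[c] for c in reversed(pattern))
        expected = set()
        for pat in (pattern, rc_pattern):
            for i in range(len(seq) - len(pat) + 1):
                if all(seq[i + j] in iupac[pat[j]] for j in range(len(pat))):
                    expected.add(i)
        found = {iv.start for iv in pchic.scan_motif_sites(seq, "chrS", pattern)}
        assert found == expected
        assert {20, 120} <= found

    def test_planted_distal_ctcf_probes_found(self, default_dataset):
        ds = default_dataset
        distal = sorted(ds.truth.distal_links)
        hits = pchic.ctcf_overlap(distal, ds.manifest, motif_sites=ds.motif_track)
        assert len(hits) == 4
        assert hits <= set(distal)
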