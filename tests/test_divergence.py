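import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from yorigin.datamodel import Window
from yorigin.divergence import (classify_sites, ils_vs_introgression_test,
                                ng86_pairwise, private_substitutions,
                                window_dxy)

from .conftest import make_matrix

W = Window("chr1", 0, 1000)


# ---------------------------------------------------------------------------
# independent NG86 oracle (built on biopython's translation, structured
# differently from the implementation: explicit path enumeration per codon
# pair, no caching, fractional site counts recomputed from scratch)
# ---------------------------------------------------------------------------

def _aa(codon):
    return str(Seq(codon).translate())


def oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if _aa(mut) != "*" and _aa(mut) == _aa(codon):
                syn += 1 / 3
    return 3 - syn, syn


def oracle_path_counts(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur, nd, sd, valid = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*" and nxt != c2:
                valid = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            paths.append((nd, sd))
    if not paths:  # all paths hit a stop: fall back to unrestricted
        for order in itertools.permutations(positions):
            cur, nd, sd = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _aa(nxt) == _aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((nd, sd))
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_ng86(a, b):
    n_s = s_s = nd = sd = 0.0
    for k in range(len(a) // 3):
        ca, cb = a[3 * k:3 * k + 3], b[3 * k:3 * k + 3]
        n1, s1 = oracle_sites(ca)
        n2, s2 = oracle_sites(cb)
        n_s += (n1 + n2) / 2
        s_s += (s1 + s2) / 2
        d_n, d_s = oracle_path_counts(ca, cb)
        nd += d_n
        sd += d_s
    pn, ps = nd / n_s, sd / s_s

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return n_s, s_s, nd, sd, jc(pn), jc(ps)


def random_cds(rng, n_codons):
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), 3))
        if _aa(c) != "*":
            codons.append(c)
    return "".join(codons)


def mutate_cds(rng, cds, p=0.04):
    seq = list(cds)
    for i in range(len(seq)):
        if rng.random() < p:
            seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
        # keep the frame stop-free
        if i % 3 == 2 and _aa("".join(seq[i - 2:i + 1])) == "*":
            seq[i - 2:i + 1] = list(cds[i - 2:i + 1])
    return "".join(seq)


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_pairwise("ATGAAA", "ATGAAA")
        assert r.dn == 0 and r.ds == 0 and r.nd == 0 and r.sd == 0

    def test_single_synonymous_change(self):
        r = ng86_pairwise("TTT", "TTC")  # Phe -> Phe
        assert r.sd == 1 and r.nd == 0

    def test_single_nonsynonymous_change(self):
        r = ng86_pairwise("TTT", "TTA")  # Phe -> Leu
        assert r.nd == 1 and r.sd == 0

    def test_sites_sum_to_three_per_codon(self):
        r = ng86_pairwise("ATGAAATTT", "ATGAAATTT")
        assert r.n_sites + r.s_sites == pytest.approx(9.0)

    def test_symmetry(self, rng):
        a = random_cds(rng, 40)
        b = mutate_cds(rng, a)
        r1, r2 = ng86_pairwise(a, b), ng86_pairwise(b, a)
        assert r1.nd == pytest.approx(r2.nd, abs=1e-12)
        assert r1.sd == pytest.approx(r2.sd, abs=1e-12)
        assert r1.dn == pytest.approx(r2.dn, abs=1e-12)

    def test_matches_pathway_enumeration_oracle(self, rng):
        for _ in range(100):
            a = random_cds(rng, 30)
            b = mutate_cds(rng, a, p=0.06)
            got = ng86_pairwise(a, b)
            n_s, s_s, nd, sd, dn, ds = oracle_ng86(a, b)
            assert got.n_sites == pytest.approx(n_s, abs=1e-12)
            assert got.s_sites == pytest.approx(s_s, abs=1e-12)
            assert got.nd == pytest.approx(nd, abs=1e-12)
            assert got.sd == pytest.approx(sd, abs=1e-12)
            if not math.isnan(dn):
                assert got.dn == pytest.approx(dn, abs=1e-12)
            if not math.isnan(ds):
                assert got.ds == pytest.approx(ds, abs=1e-12)

    def test_length_and_stop_validation(self):
        with pytest.raises(ValueError):
            ng86_pairwise("ATG", "ATGAAA")
        with pytest.raises(ValueError):
            ng86_pairwise("ATGA", "ATGA")
        with pytest.raises(ValueError, match="stop"):
            ng86_pairwise("TAAAAA", "TAAAAA")  # internal stop
        # shared terminal stop is tolerated
        r = ng86_pairwise("ATGTAA", "ATGTAA")
        assert r.nd == 0

    def test_gapped_codons_skipped(self):
        r = ng86_pairwise("ATG---TTT", "ATGAAATTC")
        assert r.n_sites + r.s_sites == pytest.approx(6.0)
        assert r.sd == 1


class TestWindowDxy:
    def test_identical_fixed_groups_zero(self):
        hm = make_matrix(np.ones((5, 4), dtype=np.int8),
                         [f"h{i}_A" for i in range(4)])
        assert window_dxy(hm, hm.hap_ids[:2], hm.hap_ids[2:], W) == 0.0

    def test_single_fixed_difference(self):
        alleles = np.array([[1, 1, 0, 0]], dtype=np.int8)
        hm = make_matrix(alleles, [f"h{i}_A" for i in range(4)])
        assert window_dxy(hm, hm.hap_ids[:2], hm.hap_ids[2:], W) == \
            pytest.approx(1 / 1000)

    def test_matches_average_pairwise_hamming(self, rng):
        for _ in range(100):
            n_sites = int(rng.integers(1, 40))
            alleles = rng.integers(0, 2, (n_sites, 10)).astype(np.int8)
            hm = make_matrix(alleles, [f"h{i}_A" for i in range(10)])
            ga, gb = hm.hap_ids[:4], hm.hap_ids[4:]
            got = window_dxy(hm, ga, gb, W)
            total = 0.0
            for x in hm.hap_indices(ga):
                for y in hm.hap_indices(gb):
                    total += (alleles[:, x] != alleles[:, y]).sum()
            want = total / (len(ga) * len(gb)) / 1000
            assert got == pytest.approx(want, abs=1e-12)


class TestIlsTest:
    def test_identical_distributions_favor_introgression(self, rng):
        vals = rng.normal(0.02, 0.001, size=40)
        res = ils_vs_introgression_test(vals, vals)
        assert res.classification == "introgression_consistent"
        assert 0.3 < res.p_value < 0.7

    def test_elevated_sdr_flags_ils(self, rng):
        sdr = rng.normal(0.05, 0.002, size=30)
        auto = rng.normal(0.02, 0.002, size=30)
        res = ils_vs_introgression_test(sdr, auto)
        assert res.classification == "ils_consistent"
        assert res.mean_difference > 0

    def test_reduced_sdr_flags_introgression(self, rng):
        sdr = rng.normal(0.005, 0.001, size=30)
        auto = rng.normal(0.02, 0.002, size=30)
        res = ils_vs_introgression_test(sdr, auto)
        assert res.classification == "introgression_consistent"

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            ils_vs_introgression_test([0.1] * 3, [0.1] * 30)


class TestPrivateSubstitutions:
    def _groups(self):
        return {"tym": ["t1_A", "t2_A"], "sin": ["s1_A", "s2_A"],
                "punY": ["y1_A", "y2_A"]}

    def test_fixed_derived_in_one_group_is_private(self):
        ids = ["t1_A", "t2_A", "s1_A", "s2_A", "y1_A", "y2_A"]
        alleles = np.array([
            [0, 0, 0, 0, 1, 1],   # private to punY
            [0, 0, 1, 1, 1, 1],   # substitution in sin and punY: neither
            [0, 0, 0, 1, 0, 0],   # sin at 0.5: substitution, private
            [0, 0, 0, 0, 0, 0],   # absent
        ], dtype=np.int8)
        hm = make_matrix(alleles, ids)
        priv = private_substitutions(hm, self._groups())
        assert priv["punY"].tolist() == [0]
        assert priv["sin"].tolist() == [2]
        assert priv["tym"].tolist() == []

    def test_classification_partitions_every_site(self):
        ids = ["t1_A", "t2_A", "s1_A", "s2_A", "y1_A", "y2_A"]
        rng = np.random.default_rng(3)
        alleles = rng.integers(0, 2, (50, 6)).astype(np.int8)
        hm = make_matrix(alleles, ids)
        cls = classify_sites(hm, self._groups())
        assert len(cls) == 50
        assert set(cls) <= {"absent", "shared", "private:tym",
                            "private:sin", "private:punY"}

    def test_simulated_truth_mutations_recovered(self, small_intro_ds):
        # in the SDR, mutations private to the male-limited clade must be
        # found on the true Y haplotypes
        ds = small_intro_ds
        cfg = ds.config
        hm = ds.haplotypes[cfg.sex_chrom]
        md = ds.metadata
        males = md.select(species="pungitius", sex="male")
        y_ids = [f"{m}_{ds.truth.y_hap[m]}" for m in males]
        x_ids = [f"{m}_{'B' if ds.truth.y_hap[m] == 'A' else 'A'}"
                 for m in males] + \
            [f"{s}_{ab}" for s in md.select(species="pungitius",
                                            sex="female") for ab in "AB"]
        groups = {
            "tym": [f"{s}_{ab}" for s in md.select(species="tymensis")
                    for ab in "AB"],
            "sin": [f"{s}_{ab}" for s in md.select(species="sinensis")
                    for ab in "AB"],
            "punX": x_ids, "punY": y_ids,
        }
        priv = private_substitutions(hm, groups)
        # Y-private substitutions exist and lie mostly inside the SDR
        assert len(priv["punY"]) > 50
        inside = ((priv["punY"] >= cfg.sdr_start)
                  & (priv["punY"] < cfg.sdr_end)).mean()
        assert inside > 0.9
        # private sets are disjoint between groups
        sets = [set(v.tolist()) for v in priv.values()]
        for a, b in itertools.combinations(sets, 2):
            assert not (a & b)
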