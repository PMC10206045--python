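"""NG86 counting, checked against a brute-force pathway-enumeration oracle
and cross-checked against an independent third-party implementation."""
import math
import warnings
from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq

from wrkykit import kaks as kk
from wrkykit import simulate as sim
from wrkykit.io import WrkykitError

GENETIC_CODE = {}  # built via Bio.Seq translation, independent of kaks.CODON_AA
for n1 in "ACGT":
    for n2 in "ACGT":
        for n3 in "ACGT":
            c = n1 + n2 + n3
            GENETIC_CODE[c] = str(Seq(c).translate())

STOPS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


def oracle_sites(codon):
    """Synonymous sites by direct neighbor enumeration."""
    s = 0.0
    for pos in range(3):
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            nb = codon[:pos] + nuc + codon[pos + 1 :]
            if nb not in STOPS and GENETIC_CODE[nb] == GENETIC_CODE[codon]:
                s += 1 / 3
    return s


def oracle_diffs(ca, cb):
    """Average pathway step counts, or None when all pathways hit stops."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in permutations(diff):
        cur, sd, nd = ca, 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_counts(codons_a, codons_b):
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d = oracle_diffs(ca, cb)
        if d is None:
            continue
        s = (oracle_sites(ca) + oracle_sites(cb)) / 2
        S, N = S + s, N + 3 - s
        Sd, Nd = Sd + d[0], Nd + d[1]
    return S, N, Sd, Nd


def random_codons(rng, n):
    out = []
    while len(out) < n:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in STOPS:
            out.append(c)
    return out


class TestBacktranslate:
    def test_gap_threading(self):
        aln = kk.backtranslate(
            (("a", "M-A"), ("b", "MKA")), {"a": "ATGGCT", "b": "ATGAAAGCC"}
        )
        assert aln.codons_a == ["ATG", "---", "GCT"]
        assert aln.codons_b == ["ATG", "AAA", "GCC"]

    def test_terminal_stop_stripped(self):
        aln = kk.backtranslate(
            (("a", "MA"), ("b", "MA")), {"a": "ATGGCTTAA", "b": "ATGGCC"}
        )
        assert aln.codons_a == ["ATG", "GCT"]

    def test_internal_stop_is_error(self):
        with pytest.raises(WrkykitError, match="stop"):
            kk.backtranslate(
                (("a", "MKA"), ("b", "MKA")),
                {"a": "ATGTAAGCT", "b": "ATGAAAGCC"},
            )

    def test_translation_mismatch_reports_position(self):
        with pytest.raises(WrkykitError, match="position 1"):
            kk.backtranslate(
                (("a", "MKA"), ("b", "MKA")),
                {"a": "ATGGGGGCT", "b": "ATGAAAGCC"},
            )

    def test_round_trip_translation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            codons = random_codons(rng, 30)
            dna = "".join(codons)
            prot = "".join(GENETIC_CODE[c] for c in codons)
            aln = kk.backtranslate((("a", prot), ("b", prot)), {"a": dna, "b": dna})
            back = "".join(GENETIC_CODE[c] for c in aln.codons_a)
            assert back == prot


class TestNg86:
    def test_identical_sequences(self):
        codons = ["ATG", "GCT", "AAA"]
        r = kk.ng86_pair(kk.CodonAlignment("a", "b", codons, codons))
        assert r.Ka == 0 and r.Ks == 0 and r.ratio is None
        assert r.category == "undefined"

    def test_single_synonymous_third_position_change(self):
        rng = np.random.default_rng(4)
        codons = random_codons(rng, 19) + ["GCT"]
        other = codons[:-1] + ["GCC"]  # Ala GCT->GCC, synonymous
        r = kk.ng86_pair(kk.CodonAlignment("a", "b", codons, other))
        S, N, Sd, Nd = oracle_counts(codons, other)
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.S == pytest.approx(S) and r.N == pytest.approx(N)
        assert r.Ka == 0 and r.Ks > 0 and r.Ka < r.Ks

    def test_site_conservation(self):
        rng = np.random.default_rng(9)
        a, b = random_codons(rng, 50), random_codons(rng, 50)
        r = kk.ng86_pair(kk.CodonAlignment("a", "b", a, b))
        assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            a, b = random_codons(rng, 20), random_codons(rng, 20)
            r1 = kk.ng86_pair(kk.CodonAlignment("a", "b", a, b))
            r2 = kk.ng86_pair(kk.CodonAlignment("b", "a", b, a))
            assert (r1.S, r1.N, r1.Sd, r1.Nd, r1.Ka, r1.Ks) == (
                r2.S, r2.N, r2.Sd, r2.Nd, r2.Ka, r2.Ks,
            )

    def test_matches_pathway_oracle_on_short_alignments(self):
        """1000 random <=5-codon alignments: Sd/Nd/S/N equal brute force."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(1, 6))
            a, b = random_codons(rng, n), random_codons(rng, n)
            S, N, Sd, Nd = oracle_counts(a, b)
            if S == 0 and N == 0:
                continue  # every column stop-blocked; ng86_pair refuses
            r = kk.ng86_pair(kk.CodonAlignment("a", "b", a, b))
            assert r.Sd == pytest.approx(Sd, abs=1e-9)
            assert r.Nd == pytest.approx(Nd, abs=1e-9)
            assert r.S == pytest.approx(S, abs=1e-9)
            assert r.N == pytest.approx(N, abs=1e-9)

    def test_agrees_with_independent_implementation(self):
        """Cross-check Ka/Ks against Biopython's NG86 on diverged pairs.

        Restricted to codon columns whose substitution pathways never touch
        a stop codon: there the two tools share one convention (this
        package excludes stop-passing pathways, Biopython keeps them).
        The stop-exclusion branch itself is pinned by the enumeration
        oracle above.
        """
        from itertools import permutations as _perms

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        def stop_free(ca, cb):
            diff = [i for i in range(3) if ca[i] != cb[i]]
            for order in _perms(diff):
                cur = ca
                for pos in order:
                    cur = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    if cur in STOPS:
                        return False
            return True

        pairs, _ = sim.gen_codon_pairs(5, 80, omega=0.4, branch_length=0.1, seed=13)
        checked = 0
        for a, b in pairs:
            ca = [a.seq[i : i + 3] for i in range(0, len(a.seq), 3)]
            cb = [b.seq[i : i + 3] for i in range(0, len(b.seq), 3)]
            keep = [(x, y) for x, y in zip(ca, cb) if stop_free(x, y)]
            ka, kb = [x for x, _ in keep], [y for _, y in keep]
            r = kk.ng86_pair(kk.CodonAlignment(a.id, b.id, ka, kb))
            dn, ds = cal_dn_ds(
                CodonSeq("".join(ka)), CodonSeq("".join(kb)), method="NG86"
            )
            assert r.Ka == pytest.approx(dn, abs=1e-9)
            assert r.Ks == pytest.approx(ds, abs=1e-9)
            checked += 1
        assert checked == 5

    def test_jukes_cantor_saturation_flagged(self):
        assert kk.jukes_cantor(0.8) is None
        assert kk.jukes_cantor(0.0) == 0.0
        p = 0.3
        assert kk.jukes_cantor(p) == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))


class TestSelectionCategory:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.3, "purifying"), (1.0, "neutral"), (1.04, "neutral"), (2.0, "positive"),
         (None, "undefined")],
    )
    def test_trichotomy(self, ratio, expected):
        assert kk.selection_category(ratio) == expected

    def test_negative_ratio_rejected(self):
        with pytest.raises(WrkykitError):
            kk.selection_category(-0.1)


class TestSimulationRecovery:
    def test_low_omega_families_all_purifying(self):
        """Families evolved with omega<1 give only defined ratios < 1."""
        pairs, _ = sim.gen_codon_pairs(15, 300, omega=0.2, branch_length=0.15, seed=21)
        ratios = []
        for a, b in pairs:
            r = kk.ng86_pair(
                kk.CodonAlignment(
                    a.id, b.id,
                    [a.seq[i : i + 3] for i in range(0, len(a.seq), 3)],
                    [b.seq[i : i + 3] for i in range(0, len(b.seq), 3)],
                )
            )
            if r.ratio is not None:
                ratios.append(r.ratio)
        assert ratios and all(rt < 1 for rt in ratios)
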