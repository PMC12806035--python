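"""Intracellular drift operators: replication, segregation, bottleneck, transfer."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mtlineage import theory
from mtlineage.mito_cell import (
    MitoPopulation,
    SimConfig,
    Variant,
    bottleneck,
    divide,
    double_population,
    make_founder,
    population_from_tsv,
    population_to_tsv,
    replicate_molecule,
    segregate,
    transfer,
    true_vaf,
    variant_at,
)

from _stats import se_of_mean, se_of_proportion, se_of_sample_variance

REF = frozenset()


def strict_config(n, mu=0.0, **kw):
    return SimConfig(N=n, mu=mu, replication_mode="strict_doubling", **kw)


# ---------------------------------------------------------------------------
# founder
# ---------------------------------------------------------------------------

class TestMakeFounder:
    def test_reference_founder(self):
        cell = make_founder(SimConfig(N=100, mu=0.0), [])
        assert cell.mito.copy_number == 100
        assert true_vaf(cell.mito) == {}
        assert cell.parent_id is None and cell.n_divisions == 0

    def test_single_preexisting_variant_rounded_onto_molecules(self):
        v = variant_at(5)
        cell = make_founder(SimConfig(N=100, mu=0.0), [(v, 0.30)])
        assert true_vaf(cell.mito) == {v: 0.30}

    def test_independent_assignment_of_overlapping_variants(self, rng):
        # v1 fixed on all 10 molecules, v2 on exactly 5 of them
        v1, v2 = variant_at(3), variant_at(4)
        cell = make_founder(SimConfig(N=10, mu=0.0), [(v1, 1.0), (v2, 0.5)], rng)
        vafs = true_vaf(cell.mito)
        assert vafs == {v1: 1.0, v2: 0.5}
        for hap in cell.mito.copies:
            assert v1 in hap

    @pytest.mark.parametrize(
        "preexisting",
        [
            [(Variant(3, "A"), 1.5)],
            [(Variant(3, "A"), -0.1)],
            [(Variant(3, "A"), 0.5), (Variant(3, "C"), 0.5)],
        ],
    )
    def test_invalid_arguments_rejected(self, preexisting):
        with pytest.raises(ValueError):
            make_founder(SimConfig(N=10, mu=0.0), preexisting)


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

class TestReplicateMolecule:
    def test_zero_rate_is_identity(self, rng):
        hap = frozenset([variant_at(7)])
        assert replicate_molecule(hap, SimConfig(N=10, mu=0.0), rng) == hap

    def test_position_collision_redrawn(self, rng):
        # L=2 and the molecule already mutated at position 0: a forced new
        # variant must be redrawn onto position 1
        from mtlineage.mito_cell import _mutate

        config = SimConfig(L=2, N=10, mu=0.4)
        hap = frozenset([variant_at(0)])
        for _ in range(50):
            out = _mutate(hap, 1, config, rng)
            assert sorted(v.position for v in out) == [0, 1]

    def test_saturated_molecule_rejected(self, rng):
        from mtlineage.mito_cell import _mutate

        config = SimConfig(L=2, N=10, mu=0.4)
        hap = frozenset([variant_at(0), variant_at(1)])
        with pytest.raises(ValueError, match="every site"):
            _mutate(hap, 1, config, rng)

    def test_poisson_mutation_count(self, rng):
        """Mean and variance of de-novo counts match Poisson(mu*L) over 1e6 events."""
        config = SimConfig(mu=1e-7)  # lambda = 1.6569e-3
        lam = theory.expected_mutations_per_replication(config.mu, config.L)
        n = 1_000_000
        counts = np.array([
            len(replicate_molecule(REF, config, rng)) for _ in range(n)
        ])
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / n)
        se_var = np.sqrt((lam + 2 * lam**2) / n)  # Poisson variance-of-variance
        assert abs(counts.var() - lam) < 3 * se_var


# ---------------------------------------------------------------------------
# doubling
# ---------------------------------------------------------------------------

class TestDoublePopulation:
    def test_strict_doubling_preserves_composition(self, rng):
        v = variant_at(9)
        cell = make_founder(strict_config(10), [(v, 0.3)], rng)
        doubled = double_population(cell.mito, strict_config(10), rng)
        assert doubled.copy_number == 20
        assert true_vaf(doubled) == {v: 0.3}

    def test_wrong_copy_number_rejected(self, rng):
        pop = MitoPopulation({REF: 7})
        with pytest.raises(ValueError, match="copy_number"):
            double_population(pop, strict_config(10), rng)

    def test_relaxed_doubling_unbiased_with_extra_drift(self, rng):
        """Relaxed replication keeps E[VAF] = p but adds replication noise."""
        v = variant_at(2)
        config = SimConfig(N=10, mu=0.0, replication_mode="relaxed")
        founder = make_founder(config, [(v, 0.5)], rng)
        n = 100_000
        vafs = np.empty(n)
        for i in range(n):
            doubled = double_population(founder.mito, config, rng)
            vafs[i] = true_vaf(doubled).get(v, 0.0)
        assert abs(vafs.mean() - 0.5) < 3 * se_of_mean(vafs)
        assert vafs.var() > 0.0


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

class TestSegregate:
    def test_homoplasmic_split(self, rng):
        d1, d2 = segregate(MitoPopulation({REF: 20}), rng)
        assert d1.copies == {REF: 10} and d2.copies == {REF: 10}

    def test_odd_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            segregate(MitoPopulation({REF: 21}), rng)

    def test_hypergeometric_variance(self, rng):
        """Daughter VAF variance matches p(1-p)/(2N-1) for N=10, p=0.5."""
        v = variant_at(0)
        mutant = frozenset([v])
        pool = MitoPopulation({REF: 10, mutant: 10})
        n = 30_000
        vafs = np.empty(n)
        for i in range(n):
            d1, _ = segregate(pool, rng)
            vafs[i] = true_vaf(d1).get(v, 0.0)
        expected = theory.segregation_variance(0.5, 10)
        assert abs(vafs.var() - expected) < 3 * se_of_sample_variance(vafs)

    @given(
        counts=st.lists(st.integers(1, 30), min_size=1, max_size=5),
        seed=st.integers(0, 2**20),
    )
    def test_conservation(self, counts, seed):
        """Daughters always partition the parent multiset exactly."""
        haps = [frozenset([variant_at(i)]) for i in range(len(counts))]
        total = sum(counts)
        if total % 2:
            counts[0] += 1
        pool = MitoPopulation(dict(zip(haps, counts)))
        d1, d2 = segregate(pool, np.random.default_rng(seed))
        merged = {h: d1.copies.get(h, 0) + d2.copies.get(h, 0) for h in pool.copies}
        assert merged == pool.copies
        assert d1.copy_number == d2.copy_number == pool.copy_number // 2


# ---------------------------------------------------------------------------
# division
# ---------------------------------------------------------------------------

class TestDivide:
    def test_fixation_is_absorbing(self, rng):
        v = variant_at(1)
        cell = make_founder(strict_config(10), [(v, 1.0)], rng)
        d1, d2 = divide(cell, strict_config(10), rng)
        assert true_vaf(d1.mito) == {v: 1.0} and true_vaf(d2.mito) == {v: 1.0}
        assert d1.n_divisions == d2.n_divisions == 1
        assert d1.parent_id == d2.parent_id == cell.cell_id
        assert d1.cell_id != d2.cell_id

    def test_neutral_drift_martingale(self, rng):
        """E[daughter VAF] = parent VAF under strict doubling, mu = 0."""
        v = variant_at(6)
        config = strict_config(10)
        cell = make_founder(config, [(v, 0.3)], rng)
        n = 100_000
        vafs = np.empty(n)
        for i in range(n):
            d1, _ = divide(cell, config, rng)
            vafs[i] = true_vaf(d1.mito).get(v, 0.0)
        assert abs(vafs.mean() - 0.3) < 3 * se_of_mean(vafs)

    def test_fixation_probability_small_chain(self, rng):
        """Neutral fixation probability equals initial frequency (N=5, p=0.2)."""
        assert theory.fixation_probability_exact(5, 1) == pytest.approx(0.2, abs=1e-9)
        config = strict_config(5)
        v = variant_at(8)
        n = 2_000
        fixed = 0
        for _ in range(n):
            cell = make_founder(config, [(v, 0.2)], rng)
            while 0.0 < true_vaf(cell.mito).get(v, 0.0) < 1.0:
                cell, _ = divide(cell, config, rng)
            fixed += true_vaf(cell.mito).get(v, 0.0) == 1.0
        p_hat = fixed / n
        assert abs(p_hat - 0.2) < 3 * se_of_proportion(p_hat, n)


# ---------------------------------------------------------------------------
# bottleneck
# ---------------------------------------------------------------------------

class TestBottleneck:
    def test_homoplasmic_composition_unchanged(self, rng):
        config = strict_config(10, bottleneck_size=9)
        v = variant_at(4)
        pop = MitoPopulation({frozenset([v]): 10})
        out = bottleneck(pop, config, rng)
        assert out.copy_number == 10
        assert true_vaf(out) == {v: 1.0}

    def test_bottleneck_size_must_be_below_n(self):
        with pytest.raises(ValueError):
            SimConfig(N=10, mu=0.0, bottleneck_size=10)

    def test_single_molecule_bottleneck_fixes_by_copy_count(self, rng):
        """b=1: the survivor haplotype is categorical in its copy counts."""
        from scipy.stats import chisquare

        config = strict_config(10, bottleneck_size=1)
        v = variant_at(4)
        pop = MitoPopulation({REF: 8, frozenset([v]): 2})  # VAF 0.2
        n = 10_000
        fixed_mut = 0
        for _ in range(n):
            out = bottleneck(pop, config, rng)
            vaf = true_vaf(out).get(v, 0.0)
            assert vaf in (0.0, 1.0)  # mu=0: homoplasmic either way
            fixed_mut += vaf == 1.0
        result = chisquare([fixed_mut, n - fixed_mut], [0.2 * n, 0.8 * n])
        assert result.pvalue > 1e-3


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------

class TestTransfer:
    def test_reference_transfer_changes_only_copy_number(self, rng):
        config = strict_config(100)
        donor = make_founder(config, [], rng)
        recipient = make_founder(config, [], rng)
        d, r = transfer(donor, recipient, 10, rng)
        assert d.mito.copy_number == 90 and r.mito.copy_number == 110
        assert true_vaf(r.mito) == {}

    def test_move_semantics_changes_both_frequencies(self, rng):
        config = strict_config(100)
        v = variant_at(11)
        donor = make_founder(config, [(v, 1.0)], rng)
        recipient = make_founder(config, [], rng)
        d, r = transfer(donor, recipient, 10, rng)
        assert true_vaf(r.mito)[v] == pytest.approx(10 / 110)
        assert true_vaf(d.mito)[v] == 1.0 and d.mito.copy_number == 90

    def test_variant_copies_conserved_across_pair(self, rng):
        config = strict_config(50)
        v1, v2 = variant_at(1), variant_at(2)
        donor = make_founder(config, [(v1, 0.4), (v2, 0.2)], rng)
        recipient = make_founder(config, [(v1, 0.1)], rng)
        before = {
            v: donor.mito.variant_counts().get(v, 0) + recipient.mito.variant_counts().get(v, 0)
            for v in (v1, v2)
        }
        d, r = transfer(donor, recipient, 20, rng)
        after = {
            v: d.mito.variant_counts().get(v, 0) + r.mito.variant_counts().get(v, 0)
            for v in (v1, v2)
        }
        assert after == before

    def test_oversized_transfer_rejected(self, rng):
        config = strict_config(10)
        donor = make_founder(config, [], rng)
        with pytest.raises(ValueError):
            transfer(donor, donor, 10, rng)


# ---------------------------------------------------------------------------
# readout and serialization
# ---------------------------------------------------------------------------

class TestTrueVaf:
    def test_examples(self):
        v1, v2 = variant_at(1), variant_at(2)
        assert true_vaf(MitoPopulation({REF: 10})) == {}
        assert true_vaf(MitoPopulation({REF: 7, frozenset([v1]): 3})) == {v1: 0.3}
        pop = MitoPopulation({
            frozenset([v1]): 2,
            frozenset([v1, v2]): 2,
            REF: 6,
        })
        assert true_vaf(pop) == {v1: 0.4, v2: 0.2}

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            MitoPopulation({})


def test_population_tsv_round_trip(rng):
    config = SimConfig(N=30, mu=1e-3)
    cell = make_founder(config, [(variant_at(3), 0.4)], rng)
    d1, _ = divide(cell, config, rng)
    text = population_to_tsv(d1.mito)
    assert population_from_tsv(text) == d1.mito


def test_division_deterministic_under_seed():
    """Identical config + seed reproduce the division bit-exactly."""
    config = SimConfig(N=50, mu=1e-4, seed=77)
    outs = []
    for _ in range(2):
        cell = make_founder(config, [(variant_at(5), 0.5)])
        d1, d2 = divide(cell, config)
        outs.append((population_to_tsv(d1.mito), population_to_tsv(d2.mito)))
    assert outs[0] == outs[1]
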