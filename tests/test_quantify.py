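"""The quantification chain: each stage against hand arithmetic, plus
structural properties (conservation, equivariance, cross-rank additivity)."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikequant import (
    ConfigurationError,
    ProfileError,
    Rank,
    RelativeAbundanceProfile,
    SpikeDominatesSampleError,
    SpikeInProtocol,
    SpikeInSpeciesSpec,
    SpikeNotDetectedError,
    Taxon,
    TaxonLineage,
    absolute_abundance,
    adjusted_total_cells,
    average_cell_estimates,
    copies_added_per_species,
    copies_to_cells,
    paper_rounded_rescale,
    phylum_adjust,
    quantify_sample,
    remove_and_rescale,
    rescale_factor,
    spikein_cells_in_sample,
    total_copies_from_spike,
)
from spikequant.examples import LACTOBACILLUS_DELBRUECKII
from spikequant.simulate import apply_spike, generate_community, to_relative_profiles


class TestCopiesAdded:
    @pytest.mark.parametrize("cpg, expected", [(3, 300_000), (7, 700_000)])
    def test_cells_route(self, protocol, cpg, expected):
        species = next(
            s for s in protocol.species if s.copies_per_genome == cpg
        )
        assert copies_added_per_species(protocol, species) == expected

    def test_stock_route(self, protocol):
        # 6e7 copies per 20 uL of stock; 10 uL of a 100x dilution is
        # 0.1 uL of stock = 1/200 of the reference aliquot -> 300,000
        species = SpikeInSpeciesSpec(
            name="stock-only",
            lineage=TaxonLineage(phylum="Bacteroidota"),
            copies_per_genome=3,
            stock_copies_per_reference_volume=6.0e7,
        )
        assert copies_added_per_species(protocol, species) == \
            pytest.approx(300_000)

    def test_consistent_dual_route_accepted(self, protocol):
        species = SpikeInSpeciesSpec(
            name="both",
            lineage=TaxonLineage(phylum="Bacteroidota"),
            copies_per_genome=3,
            cells_added=100_000,
            stock_copies_per_reference_volume=6.0e7,
        )
        assert copies_added_per_species(protocol, species) == 300_000

    def test_contradictory_dual_route_rejected(self, protocol):
        species = SpikeInSpeciesSpec(
            name="both",
            lineage=TaxonLineage(phylum="Bacteroidota"),
            copies_per_genome=3,
            cells_added=100_000,
            stock_copies_per_reference_volume=5.0e7,
        )
        with pytest.raises(ConfigurationError, match="disagree"):
            copies_added_per_species(protocol, species)


class TestStageArithmetic:
    @pytest.mark.parametrize("percent, copies, expected", [
        (1.0, 300_000, 3.0e7),
        (3.0, 700_000, 700_000 / 0.03),
        (100.0, 12345.0, 12345.0),
    ])
    def test_total_copies(self, percent, copies, expected):
        assert total_copies_from_spike(percent, copies) == \
            pytest.approx(expected, rel=1e-12)

    def test_total_copies_error_cases(self):
        with pytest.raises(SpikeNotDetectedError):
            total_copies_from_spike(0.0, 1e5)
        with pytest.raises(ProfileError):
            total_copies_from_spike(101.0, 1e5)

    @pytest.mark.parametrize("copies, mean, expected", [
        (3.0e7, 5, 6.0e6),
        (700_000 / 0.03, 5, 700_000 / 0.03 / 5),
        (42.0, 1, 42.0),
    ])
    def test_copies_to_cells(self, copies, mean, expected):
        assert copies_to_cells(copies, mean) == pytest.approx(expected)

    def test_average_of_worked_example_estimates(self):
        assert average_cell_estimates([6.0e6, 700_000 / 0.03 / 5]) == \
            pytest.approx(16.0e6 / 3, rel=1e-12)

    def test_average_single_estimate_is_identity(self):
        assert average_cell_estimates([7.7e5]) == 7.7e5

    @given(st.lists(st.floats(min_value=1, max_value=1e9), min_size=1,
                    max_size=6))
    def test_average_between_min_and_max(self, estimates):
        avg = average_cell_estimates(estimates)
        assert min(estimates) <= avg <= max(estimates)

    @pytest.mark.parametrize("percent, avg, expected", [
        (1.0, 16e6 / 3, 16e6 / 300),
        (3.0, 16e6 / 3, 0.16e6),
        (0.0, 5.0e6, 0.0),
    ])
    def test_spike_cells_in_sample(self, percent, avg, expected):
        assert spikein_cells_in_sample(percent, avg) == \
            pytest.approx(expected, rel=1e-12)

    def test_adjusted_total_worked_example(self):
        avg = 16e6 / 3
        assert adjusted_total_cells(avg, [avg * 0.01, avg * 0.03]) == \
            pytest.approx(5.12e6, rel=1e-12)

    def test_adjusted_total_boundaries(self):
        assert adjusted_total_cells(5.0, []) == 5.0
        assert adjusted_total_cells(5.0, [5.0]) == 0.0
        with pytest.raises(SpikeDominatesSampleError, match="dominates"):
            adjusted_total_cells(5.0, [6.0])


class TestRemoveAndRescale:
    def test_worked_example_value(self, species_profile, protocol):
        adjusted = remove_and_rescale(
            species_profile, protocol.spike_taxa(Rank.SPECIES)
        )
        value = adjusted.abundances[LACTOBACILLUS_DELBRUECKII]
        assert value == pytest.approx(46.875, rel=1e-12)
        assert round(value, 2) == 46.88
        assert round(rescale_factor(4.0), 3) == 1.042

    def test_empty_spike_set_is_identity(self, species_profile):
        assert remove_and_rescale(species_profile, []) is species_profile

    def test_spike_absent_raises(self, species_profile):
        ghost = Taxon(label="Ghost", lineage=TaxonLineage(phylum="Nope"))
        with pytest.raises(SpikeNotDetectedError, match="Nope"):
            remove_and_rescale(species_profile, [ghost])

    @given(
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=3,
                 max_size=10),
        st.integers(min_value=1, max_value=2),
    )
    def test_matches_renormalization_oracle(self, raw, n_spikes):
        """Each kept taxon ends at p*100/(100-s); the result renormalizes
        to 100 — checked against an independent normalize-by-sum oracle."""
        total = sum(raw)
        percents = [100 * v / total for v in raw]
        taxa = [Taxon(label=f"t{i}") for i in range(len(percents))]
        profile = RelativeAbundanceProfile(
            sample_id="x", rank=Rank.SPECIES,
            abundances=dict(zip(taxa, percents)),
        )
        spikes = taxa[:n_spikes]
        adjusted = remove_and_rescale(profile, spikes)
        kept = percents[n_spikes:]
        oracle = [100 * v / sum(kept) for v in kept]
        for taxon, expect in zip(taxa[n_spikes:], oracle):
            assert adjusted.abundances[taxon] == pytest.approx(
                expect, rel=1e-9
            )
        assert adjusted.total() == pytest.approx(100, abs=1e-9)


class TestPhylumAdjust:
    def test_worked_example_exact_and_display(self, worked_profiles, protocol):
        spikes = {"Imtechella halotolerans": 1.0,
                  "Allobacillus halotolerans": 3.0}
        lineages = {s.name: s.lineage for s in protocol.species}
        adjusted = phylum_adjust(
            worked_profiles[Rank.PHYLUM], spikes, lineages
        )
        bacteroidota = Taxon(
            label="Bacteroidota", lineage=TaxonLineage(phylum="Bacteroidota")
        )
        value = adjusted.abundances[bacteroidota]
        assert value == pytest.approx(49 * 100 / 96, rel=1e-12)  # 51.0417%
        assert adjusted.total() == pytest.approx(100, abs=1e-9)
        # display convention with the factor pre-rounded to 3 decimals
        assert paper_rounded_rescale(49.0, 4.0) == 51.06

    def test_no_spikes_is_identity(self, worked_profiles):
        profile = worked_profiles[Rank.PHYLUM]
        assert phylum_adjust(profile, {}, {}) is profile

    def test_spike_exceeding_its_phylum_raises(self, worked_profiles, protocol):
        lineages = {s.name: s.lineage for s in protocol.species}
        with pytest.raises(ProfileError, match="exceeds its phylum"):
            phylum_adjust(
                worked_profiles[Rank.PHYLUM],
                {"Imtechella halotolerans": 60.0},
                lineages,
            )

    def test_clamp_within_tolerance(self, protocol):
        lineages = {s.name: s.lineage for s in protocol.species}
        profile = RelativeAbundanceProfile(
            sample_id="x", rank=Rank.PHYLUM,
            abundances={
                Taxon(label="Bacteroidota",
                      lineage=TaxonLineage(phylum="Bacteroidota")): 1.0,
                Taxon(label="Bacillota",
                      lineage=TaxonLineage(phylum="Bacillota")): 99.0,
            },
        )
        adjusted = phylum_adjust(
            profile, {"Imtechella halotolerans": 1.0 + 1e-12}, lineages,
        )
        bacteroidota = Taxon(
            label="Bacteroidota", lineage=TaxonLineage(phylum="Bacteroidota")
        )
        assert adjusted.abundances[bacteroidota] == 0.0


class TestFullChain:
    def test_worked_example_end_to_end(self, worked_profiles, protocol):
        quant, table = quantify_sample(worked_profiles, protocol, Rank.SPECIES)
        assert quant.adjusted_total_cells == pytest.approx(5.12e6, rel=1e-12)
        assert table.cells[LACTOBACILLUS_DELBRUECKII] == \
            pytest.approx(2.4e6, rel=1e-12)
        assert table.total_cells() == pytest.approx(
            quant.adjusted_total_cells, rel=1e-9
        )
        # intermediates recorded per spike species
        by_name = {e.species: e for e in quant.spike_estimates}
        imtechella = by_name["Imtechella halotolerans"]
        assert imtechella.total_copies_estimate == pytest.approx(3.0e7)
        assert imtechella.cells_estimate == pytest.approx(6.0e6)

    def test_pure_spike_sample_gives_zero_totals(self, protocol):
        imtechella, allobacillus = (s.taxon for s in protocol.species)
        profiles = {
            Rank.SPECIES: RelativeAbundanceProfile(
                sample_id="pure", rank=Rank.SPECIES,
                abundances={imtechella: 25.0, allobacillus: 75.0,
                            Taxon(label="Native"): 0.0},
            )
        }
        quant, table = quantify_sample(profiles, protocol, Rank.SPECIES)
        assert quant.adjusted_total_cells == pytest.approx(0.0, abs=1e-6)
        assert table.cells[Taxon(label="Native")] == pytest.approx(0, abs=1e-6)

    def test_scale_equivariance(self, worked_profiles, protocol):
        """Multiplying every spike dose by c multiplies every absolute
        abundance by c."""
        c = 3.5
        scaled = SpikeInProtocol(
            species=tuple(
                SpikeInSpeciesSpec(
                    name=s.name, lineage=s.lineage,
                    copies_per_genome=s.copies_per_genome,
                    cells_added=s.cells_added * c,
                )
                for s in protocol.species
            ),
            volume_added=protocol.volume_added,
            dilution_factor=protocol.dilution_factor,
            reference_volume=protocol.reference_volume,
        )
        _, base = quantify_sample(worked_profiles, protocol, Rank.SPECIES)
        _, big = quantify_sample(worked_profiles, scaled, Rank.SPECIES)
        for taxon, cells in base.cells.items():
            assert big.cells[taxon] == pytest.approx(c * cells, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=20),
           st.floats(min_value=0.1, max_value=20))
    def test_inverse_monotonicity(self, a, b):
        """A larger observed spike percent means fewer total copies."""
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert total_copies_from_spike(hi, 3e5) < \
            total_copies_from_spike(lo, 3e5)

    def test_single_spike_reduces_to_internal_standard_formula(self, protocol):
        """With one spike the chain is the classic single-internal-standard
        estimate: total = dose/(fraction) then spike-free remainder."""
        species = protocol.species[0]
        single = SpikeInProtocol(species=(species,))
        native = Taxon(label="Native")
        profiles = {
            Rank.SPECIES: RelativeAbundanceProfile(
                sample_id="s", rank=Rank.SPECIES,
                abundances={species.taxon: 2.0, native: 98.0},
            )
        }
        quant, table = quantify_sample(profiles, single, Rank.SPECIES)
        total = (100_000 * 3) / 0.02 / 5
        assert quant.average_cells_estimate == pytest.approx(total)
        assert table.cells[native] == pytest.approx(total * 0.98, rel=1e-12)

    def test_cross_rank_additivity(self, protocol):
        """Genus-level cells equal the sum of member species' cells when
        both ranks derive from the same underlying community."""
        community = generate_community(
            n_taxa=27, total_cells=4e6, concentration=0.5, seed=11
        )
        spiked = apply_spike(community, protocol)
        profiles = to_relative_profiles(spiked, exact=True)
        _, species_table = quantify_sample(profiles, protocol, Rank.SPECIES)
        _, genus_table = quantify_sample(profiles, protocol, Rank.GENUS)
        rollup: dict[Taxon, float] = {}
        for taxon, cells in species_table.cells.items():
            rollup.setdefault(taxon.at_rank(Rank.GENUS), 0.0)
            rollup[taxon.at_rank(Rank.GENUS)] += cells
        assert set(rollup) == set(genus_table.cells)
        for taxon, cells in genus_table.cells.items():
            assert rollup[taxon] == pytest.approx(cells, rel=1e-9)

    def test_per_taxon_copy_correction_recovers_truth_exactly(self, protocol):
        """Given every native taxon's true copy number, estimates equal the
        true cell counts even in a copy-heterogeneous community."""
        community = generate_community(
            n_taxa=12, total_cells=3e6, concentration=0.5, seed=5,
            copies_per_genome=(2, 9),
        )
        spiked = apply_spike(community, protocol)
        profiles = to_relative_profiles(spiked, exact=True)
        copies = {
            t: c for t, c in zip(spiked.taxa, spiked.copies_per_genome)
        }
        _, table = quantify_sample(
            profiles, protocol, Rank.SPECIES, per_taxon_copies=copies
        )
        truth = spiked.true_cells_by_taxon()
        for taxon in spiked.native_taxa:
            assert table.cells[taxon] == pytest.approx(
                truth[taxon], rel=1e-9
            )

    def test_flat_copy_assumption_bias_is_cpg_over_five(self, protocol):
        """With heterogeneous true copy numbers but the flat-5 assumption,
        each taxon's estimate is inflated by exactly its copies/5 in exact
        observation mode — the predictable systematic bias of the method."""
        community = generate_community(
            n_taxa=10, total_cells=2e6, concentration=0.8, seed=3,
            copies_per_genome=(3, 10),
        )
        spiked = apply_spike(community, protocol)
        profiles = to_relative_profiles(spiked, exact=True)
        _, table = quantify_sample(profiles, protocol, Rank.SPECIES)
        truth = spiked.true_cells_by_taxon()
        copies = dict(zip(spiked.taxa, spiked.copies_per_genome))
        for taxon in spiked.native_taxa:
            expected = truth[taxon] * copies[taxon] / 5.0
            assert table.cells[taxon] == pytest.approx(expected, rel=1e-9)

    def test_absolute_abundance_conserves_total(self, worked_profiles,
                                                protocol):
        adjusted = remove_and_rescale(
            worked_profiles[Rank.SPECIES], protocol.spike_taxa(Rank.SPECIES)
        )
        table = absolute_abundance(adjusted, 5.12e6)
        assert table.total_cells() == pytest.approx(5.12e6, rel=1e-12)
        assert math.isclose(sum(table.adjusted_percent.values()), 100,
                            abs_tol=1e-9)
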