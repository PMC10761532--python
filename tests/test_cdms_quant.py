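import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from aavpack.cdms_quant import (
    UNASSIGNED_LABEL,
    assign_ions,
    assign_labels,
    build_spectrum,
    charge_summary,
    confusion_frame,
)
from aavpack.cdms_synth import IonEvent, MixtureSpec, SimConfig, simulate_ions
from aavpack.errors import ConfigError, EmptyInputError, InvalidArgumentError
from aavpack.genome_model import full_species_list
from aavpack.mass_model import SpeciesMassTable, build_mass_table


def ion(mass: float, charge: float = 155.0, species: str | None = None) -> IonEvent:
    return IonEvent(
        measured_mz=mass / charge,
        measured_charge=charge,
        derived_mass=mass,
        true_species=species,
    )


class TestBuildSpectrum:
    def test_single_ion_single_bin(self):
        spectrum = build_spectrum([ion(4.0e6)], bin_width=1e4)
        assert spectrum.counts.sum() == 1
        nz = np.flatnonzero(spectrum.counts)
        assert len(nz) == 1
        lo = spectrum.bin_edges[nz[0]]
        hi = spectrum.bin_edges[nz[0] + 1]
        assert lo <= 4.0e6 < hi

    def test_count_conservation_under_rebinning(self, mass_table_848):
        mix = MixtureSpec({"empty": 0.6, "1GOI-2ITR": 0.4})
        events = simulate_ions(mix, mass_table_848, SimConfig(seed=2, n_ions=3000))
        for width in (5e3, 1e4, 2e4):
            assert build_spectrum(events, width).counts.sum() == 3000

    def test_noise_free_two_species_two_bins(self, mass_table_848):
        mix = MixtureSpec({"empty": 0.5, "2GOI-3ITR": 0.5})
        sim = SimConfig(seed=3, n_ions=400, charge_sigma=0.0, mz_cv=0.0)
        events = simulate_ions(mix, mass_table_848, sim)
        spectrum = build_spectrum(events, bin_width=1e4)
        assert np.count_nonzero(spectrum.counts) == 2

    def test_rejects_empty_input(self):
        with pytest.raises(EmptyInputError):
            build_spectrum([])

    def test_rejects_bad_bin_width(self):
        with pytest.raises(InvalidArgumentError):
            build_spectrum([ion(1e6)], bin_width=0)

    def test_edges_strictly_increasing(self, mass_table_848):
        mix = MixtureSpec({"empty": 1.0})
        events = simulate_ions(mix, mass_table_848, SimConfig(seed=1, n_ions=50))
        spectrum = build_spectrum(events)
        assert (np.diff(spectrum.bin_edges) > 0).all()


class TestAssignIons:
    def test_noise_free_assignment_is_exact(self, mass_table_848):
        mix = MixtureSpec({"empty": 0.7, "1GOI-2ITR": 0.2, "3GOI-4ITR": 0.1})
        sim = SimConfig(seed=4, n_ions=5000, charge_sigma=0.0, mz_cv=0.0)
        events = simulate_ions(mix, mass_table_848, sim)
        quant = assign_ions(events, mass_table_848)
        confusion = confusion_frame(events, quant)
        for label in mix.labels:
            assert confusion.loc[label, label] == sum(
                e.true_species == label for e in events
            )
        assert quant.unassigned_count == 0

    def test_boundary_goes_to_lower_species(self, construct_848, capsid, mass_params):
        table = build_mass_table(
            full_species_list(construct_848), capsid, mass_params,
            window_half_width=0.25,  # forces midpoint-clipped shared edges
        )
        boundary = table.rows[0].window_high
        assert boundary == table.rows[1].window_low
        labels = assign_labels([ion(boundary)], table)
        assert labels[0] == table.rows[0].label

    def test_count_conservation(self, mass_table_848):
        rng = np.random.default_rng(0)
        events = [ion(m) for m in rng.uniform(1e6, 6e6, size=500)]
        quant = assign_ions(events, mass_table_848)
        assert sum(quant.ion_counts.values()) + quant.unassigned_count == 500
        assert sum(quant.rel_abundances.values()) == pytest.approx(1.0, abs=1e-9)

    @settings(
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(seed=st.integers(0, 10_000))
    def test_count_conservation_property(self, mass_table_848, seed):
        rng = np.random.default_rng(seed)
        masses = rng.uniform(0.5e6, 7e6, size=64)
        quant = assign_ions([ion(m) for m in masses], mass_table_848)
        assert sum(quant.ion_counts.values()) + quant.unassigned_count == 64

    def test_window_assignment_matches_nearest_mass(
        self, construct_848, capsid, mass_params
    ):
        # with fully midpoint-clipped windows, window membership must agree
        # with brute-force nearest-predicted-mass assignment
        table = build_mass_table(
            full_species_list(construct_848), capsid, mass_params,
            window_half_width=0.5,
        )
        preds = np.array([r.predicted_mass for r in table.rows])
        rng = np.random.default_rng(1)
        masses = rng.uniform(preds[0] * 0.6, preds[-1] * 1.4, size=1000)
        labels = assign_labels([ion(m) for m in masses], table)
        for m, lab in zip(masses, labels):
            if lab == UNASSIGNED_LABEL:
                continue
            nearest = table.rows[int(np.argmin(np.abs(preds - m)))].label
            assert lab == nearest

    def test_out_of_range_counted_not_dropped(self, mass_table_848):
        low = ion(0.1 * mass_table_848.rows[0].predicted_mass)
        high = ion(2.0 * mass_table_848.rows[-1].predicted_mass)
        quant = assign_ions([low, high], mass_table_848)
        assert quant.unassigned_count == 2
        assert quant.total_ions == 2

    def test_empty_table_rejected(self):
        with pytest.raises(ConfigError):
            assign_labels([ion(1e6)], SpeciesMassTable(rows=()))

    def test_empty_events_rejected(self, mass_table_848):
        with pytest.raises(EmptyInputError):
            assign_ions([], mass_table_848)

    def test_abundance_consistency_at_50k(
        self, mass_table_848, suspension_mixture_848
    ):
        # estimator consistency: at 50,000 ions and preset noise, estimated
        # fractions sit within 0.5 percentage points of the mixture truth
        events = simulate_ions(
            suspension_mixture_848, mass_table_848,
            SimConfig(seed=17, n_ions=50_000),
        )
        quant = assign_ions(events, mass_table_848)
        for label in mass_table_848.labels:
            truth = suspension_mixture_848.fractions.get(label, 0.0)
            est = quant.rel_abundance(label)
            assert abs(est - truth) * 100.0 < 0.5, label
        truth_partial = suspension_mixture_848.fractions["partial"]
        est_unassigned = quant.unassigned_count / quant.total_ions
        assert abs(est_unassigned - truth_partial) * 100.0 < 0.5


class TestChargeSummary:
    def test_shared_charge_model_not_flagged(
        self, mass_table_848, suspension_mixture_848
    ):
        events = simulate_ions(
            suspension_mixture_848, mass_table_848,
            SimConfig(seed=21, n_ions=10_000),
        )
        quant = assign_ions(events, mass_table_848)
        summary = charge_summary(events, quant, empty_label="empty")
        assert not any(summary.flagged.values())

    def test_elevated_charge_species_flagged(self, mass_table_848):
        base = simulate_ions(
            MixtureSpec({"empty": 1.0}), mass_table_848,
            SimConfig(seed=22, n_ions=4000),
        )
        hot = simulate_ions(
            MixtureSpec({"2GOI-3ITR": 1.0}), mass_table_848,
            SimConfig(seed=23, n_ions=1000, charge_mean=260.0),  # +20 e
        )
        events = base + hot
        quant = assign_ions(events, mass_table_848)
        summary = charge_summary(events, quant, empty_label="empty")
        assert summary.flagged["2GOI-3ITR"]
        assert not summary.flagged["empty"]

    def test_single_species_mean_equals_global_mean(self, mass_table_848):
        events = simulate_ions(
            MixtureSpec({"empty": 1.0}), mass_table_848,
            SimConfig(seed=24, n_ions=500),
        )
        quant = assign_ions(events, mass_table_848)
        summary = charge_summary(events, quant, empty_label="empty")
        global_mean = np.mean([e.measured_charge for e in events])
        assert summary.mean_charge["empty"] == pytest.approx(global_mean, rel=1e-6)

    def test_zero_ion_species_absent_and_unflagged(self, mass_table_848):
        events = simulate_ions(
            MixtureSpec({"empty": 1.0}), mass_table_848,
            SimConfig(seed=25, n_ions=200),
        )
        quant = assign_ions(events, mass_table_848)
        summary = charge_summary(events, quant, empty_label="empty")
        assert summary.mean_charge["6GOI-7ITR"] is None
        assert not summary.flagged["6GOI-7ITR"]

    def test_mismatched_quant_rejected(self, mass_table_848):
        events = simulate_ions(
            MixtureSpec({"empty": 1.0}), mass_table_848,
            SimConfig(seed=26, n_ions=50),
        )
        quant = assign_ions(events, mass_table_848)
        with pytest.raises(InvalidArgumentError):
            charge_summary(events[:-1], quant)
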