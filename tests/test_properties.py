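import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldspot.errors import CompositionError, ComponentPropertyError, ParameterError
from coldspot.properties import (
    CHOI_OKOS_20C,
    COMPONENTS,
    Composition,
    ComponentProperties,
    DEFAULT_COMPOSITION,
    DEFAULT_G,
    estimate_all,
    estimate_density,
    estimate_heat_capacity,
    estimate_thermal_conductivity,
    volume_fractions,
)


def props_from_values(rho, cp=None, k=None):
    """Pack per-component scalars (aligned with COMPONENTS) into props."""
    n = len(COMPONENTS)
    rho = np.asarray(rho, float)
    cp = np.full(n, 2000.0) if cp is None else np.asarray(cp, float)
    k = np.full(n, 0.5) if k is None else np.asarray(k, float)
    return ComponentProperties(rho=rho, cp=cp, k=k)


class TestDensity:
    def test_single_component_identity(self):
        comp = Composition(water=1.0)
        props = props_from_values([997.0, 1300, 900, 1600, 2400])
        assert estimate_density(comp, props) == pytest.approx(997.0)

    def test_two_component_harmonic(self):
        # 1/(0.5/1000 + 0.5/920) = 958.333...
        comp = Composition(water=0.5, fat=0.5)
        props = props_from_values([1000.0, 1300, 920.0, 1600, 2400])
        assert estimate_density(comp, props) == pytest.approx(958.3333333, abs=1e-4)

    def test_packaged_default(self):
        got = estimate_density(DEFAULT_COMPOSITION, CHOI_OKOS_20C)
        assert got == pytest.approx(1064.5, rel=5e-3)

    def test_invalid_component_density(self):
        with pytest.raises(ComponentPropertyError):
            props_from_values([-1.0, 1300, 900, 1600, 2400])

    def test_bad_sum_rejected(self):
        with pytest.raises(CompositionError):
            Composition(water=0.5, fat=0.4)


class TestHeatCapacity:
    def test_single_component(self):
        comp = Composition(water=1.0)
        props = props_from_values([997] * 5, cp=[4180, 2000, 2000, 2000, 2000])
        assert estimate_heat_capacity(comp, props) == pytest.approx(4180.0)

    def test_weighted_mean(self):
        # 0.75*4180 + 0.25*2000 = 3635
        comp = Composition(water=0.75, protein=0.25)
        props = props_from_values([1000] * 5, cp=[4180, 2000, 0.1, 0.1, 0.1])
        assert estimate_heat_capacity(comp, props) == pytest.approx(3635.0)

    def test_packaged_default(self):
        got = estimate_heat_capacity(DEFAULT_COMPOSITION, CHOI_OKOS_20C)
        assert got == pytest.approx(3535.5, rel=5e-3)


class TestVolumeFractions:
    def test_single_component(self):
        comp = Composition(protein=1.0)
        eps = volume_fractions(comp, CHOI_OKOS_20C)
        assert eps[COMPONENTS.index("protein")] == pytest.approx(1.0)

    def test_half_half_density_ratio(self):
        # x = {0.5, 0.5}, rho = {1000, 500} -> eps = {1/3, 2/3}
        comp = Composition(water=0.5, fat=0.5)
        props = props_from_values([1000.0, 1, 500.0, 1, 1])
        eps = volume_fractions(comp, props)
        assert eps[0] == pytest.approx(1 / 3)
        assert eps[2] == pytest.approx(2 / 3)

    def test_equal_densities_identity(self):
        comp = Composition(water=0.3, protein=0.3, fat=0.4)
        props = props_from_values([1000.0] * 5)
        assert volume_fractions(comp, props) == pytest.approx(comp.as_array())

    def test_sums_to_one(self):
        eps = volume_fractions(DEFAULT_COMPOSITION, CHOI_OKOS_20C)
        assert eps.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((eps >= 0) & (eps <= 1))


class TestConductivity:
    def test_single_component_any_g(self):
        comp = Composition(ash=1.0)
        for g in (0.0, 0.3, 1.0):
            got = estimate_thermal_conductivity(comp, CHOI_OKOS_20C, g)
            assert got == pytest.approx(CHOI_OKOS_20C.k[COMPONENTS.index("ash")])

    def test_mixture_limits(self):
        # eps = {0.5, 0.5} via equal densities; k = {0.6, 0.2}
        comp = Composition(water=0.5, protein=0.5)
        props = props_from_values(
            [1000.0] * 5, k=[0.6, 0.2, 1, 1, 1]
        )
        k_per = estimate_thermal_conductivity(comp, props, g=1.0)
        k_par = estimate_thermal_conductivity(comp, props, g=0.0)
        k_mid = estimate_thermal_conductivity(comp, props, g=0.5)
        assert k_per == pytest.approx(0.30)
        assert k_par == pytest.approx(0.40)
        assert k_mid == pytest.approx(0.35)

    def test_packaged_default(self):
        got = estimate_thermal_conductivity(DEFAULT_COMPOSITION, CHOI_OKOS_20C, DEFAULT_G)
        assert got == pytest.approx(0.47, rel=5e-3)

    def test_g_out_of_range(self):
        with pytest.raises(ParameterError):
            estimate_thermal_conductivity(DEFAULT_COMPOSITION, CHOI_OKOS_20C, 1.5)


# --- property-based invariants -------------------------------------------

def compositions():
    return (
        st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5)
        .map(lambda xs: np.array(xs) / np.sum(xs))
        .map(lambda x: Composition(**dict(zip(COMPONENTS, x / x.sum()))))
    )


def component_props():
    pos = st.floats(0.05, 5000.0)
    return st.tuples(
        st.lists(st.floats(500.0, 3000.0), min_size=5, max_size=5),
        st.lists(st.floats(800.0, 4500.0), min_size=5, max_size=5),
        st.lists(st.floats(0.05, 0.8), min_size=5, max_size=5),
    ).map(lambda t: ComponentProperties(*map(np.array, t)))


@settings(max_examples=60, deadline=None)
@given(comp=compositions(), props=component_props(), g=st.floats(0.0, 1.0))
def test_harmonic_arithmetic_ordering(comp, props, g):
    eps = volume_fractions(comp, props)
    k_par = float(np.dot(eps, props.k))
    k_per = float(1.0 / np.sum(eps / props.k))
    k_mix = estimate_thermal_conductivity(comp, props, g)
    assert props.k.min() - 1e-9 <= k_per <= k_mix + 1e-9
    assert k_mix <= k_par + 1e-9 <= props.k.max() + 1e-6


@settings(max_examples=60, deadline=None)
@given(comp=compositions(), props=component_props())
def test_outputs_bounded_by_components(comp, props):
    rho = estimate_density(comp, props)
    cp = estimate_heat_capacity(comp, props)
    assert props.rho.min() - 1e-6 <= rho <= props.rho.max() + 1e-6
    assert props.cp.min() - 1e-6 <= cp <= props.cp.max() + 1e-6


@settings(max_examples=40, deadline=None)
@given(comp=compositions(), props=component_props(), g=st.floats(0.0, 1.0))
def test_permutation_invariance(comp, props, g):
    """Reordering which named slot holds which (x, rho, cp, k) tuple is a no-op."""
    rng = np.random.default_rng(0)
    perm = rng.permutation(5)
    comp_p = Composition(**dict(zip(COMPONENTS, comp.as_array()[perm])))
    props_p = ComponentProperties(
        rho=props.rho[perm], cp=props.cp[perm], k=props.k[perm]
    )
    assert estimate_density(comp_p, props_p) == pytest.approx(
        estimate_density(comp, props), rel=1e-12
    )
    assert estimate_heat_capacity(comp_p, props_p) == pytest.approx(
        estimate_heat_capacity(comp, props), rel=1e-12
    )
    assert estimate_thermal_conductivity(comp_p, props_p, g) == pytest.approx(
        estimate_thermal_conductivity(comp, props, g), rel=1e-12
    )


@settings(max_examples=40, deadline=None)
@given(
    comp=compositions(),
    props=component_props(),
    c=st.floats(0.1, 10.0),
)
def test_density_scaling_homogeneity(comp, props, c):
    scaled = ComponentProperties(rho=c * props.rho, cp=props.cp, k=props.k)
    assert estimate_density(comp, scaled) == pytest.approx(
        c * estimate_density(comp, props), rel=1e-12
    )


@pytest.mark.parametrize("name", COMPONENTS)
def test_degenerate_single_component(name):
    comp = Composition(**{name: 1.0})
    i = COMPONENTS.index(name)
    assert estimate_density(comp, CHOI_OKOS_20C) == pytest.approx(CHOI_OKOS_20C.rho[i])
    assert estimate_heat_capacity(comp, CHOI_OKOS_20C) == pytest.approx(CHOI_OKOS_20C.cp[i])
    assert estimate_thermal_conductivity(comp, CHOI_OKOS_20C, 0.7) == pytest.approx(
        CHOI_OKOS_20C.k[i]
    )


def test_estimate_all_consistency():
    tp = estimate_all(DEFAULT_COMPOSITION, CHOI_OKOS_20C, DEFAULT_G)
    assert tp.k_per <= tp.k <= tp.k_par
    assert tp.alpha == pytest.approx(tp.k / (tp.rho * tp.cp))
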