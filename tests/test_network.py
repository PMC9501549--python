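import numpy as np
import pytest

from camsignal.cam import CAM4
from camsignal.network import (CAM_BOUND, SPECIES, _kernel_fast, _make_rhs,
                               _pack, initial_state, integrate, network_rhs,
                               observables)
from camsignal.parameters import default_parameters
from camsignal.stimulus import make_protocol

IDX = {n: i for i, n in enumerate(SPECIES)}


@pytest.mark.parametrize("mode", ["reduced_pka", "full_pka"])
def test_compiled_kernel_equals_reference_closure(params, rng, mode):
    ref = _make_rhs(params, mode, "release_slow")
    K = _pack(params, mode, "release_slow")
    for _ in range(30):
        y = np.abs(rng.normal(0.5, 1.0, 25))
        ca = float(np.abs(rng.normal(1, 2)))
        assert np.array_equal(ref(0.0, y, ca), _kernel_fast(0.0, y, ca, K))


def test_quiescent_network_has_no_nontrivial_fluxes(params):
    """With target binding and CaM-independent production switched off, the
    rest state at basal Ca²⁺ produces no non-CaM dynamics."""
    p = params.replace(kc1f=0, kc2f=0, kc3f=0, kc4f=0, kc5f=0, ACstar_T=0)
    proto = make_protocol("LFS", Ca_basal=p.Ca_basal, tau=p.tau_decay)
    y0 = initial_state(p)
    d = network_rhs(proto.pulse_times[-1] + 0.999, y0, p, proto)
    assert np.allclose(d[9:], 0.0, atol=1e-12)


def test_single_target_equilibrium_bound_fraction(params):
    """With only CaMKII present and phosphorylation off, the bound fraction
    at fixed CaM₄ is the analytic single-site equilibrium."""
    p = params.replace(kc1f=0, kc2f=0, kc3f=0, kc4f=0, kcat14=0)
    cam4 = 0.8
    bound = p.CaMKII_T * p.kc5f * cam4 / (p.kc5f * cam4 + p.kc5b1)
    y = np.zeros(25)
    y[CAM4] = cam4
    y[IDX["CaMCaMKII"]] = bound
    d = _make_rhs(p, "reduced_pka", "release_slow")(0.0, y, 1.0)
    assert abs(d[IDX["CaMCaMKII"]]) < 1e-10


def test_conserved_pool_derivatives_vanish(params, rng):
    """Sum of derivatives over the CaM and PKA pools is structurally zero."""
    rhs = _make_rhs(params, "full_pka", "release_slow")
    cam_pool = list(range(9)) + [IDX[n] for n in CAM_BOUND]
    pka_pool = [IDX[n] for n in ("R2C2", "R2C2cAMP2", "R2C2cAMP4")]
    for _ in range(20):
        y = np.abs(rng.normal(0.5, 1.0, 25))
        d = rhs(0.0, y, float(rng.uniform(0, 8)))
        assert abs(sum(d[i] for i in cam_pool)) < 1e-9
        assert abs(sum(d[i] for i in pka_pool) + d[IDX["PKAc"]] / 2) < 1e-9
        # CaMKII subunits: dynamic members balance against the algebraic free pool
        k2 = d[IDX["CaMCaMKII"]] + d[IDX["CaMCaMKIIP"]] + d[IDX["CaMKIIP"]]
        assert np.isfinite(k2)


def test_nan_state_identifies_species(params):
    proto = make_protocol("LFS")
    y = initial_state(params)
    y[IDX["cAMP"]] = np.nan
    with pytest.raises(ValueError, match="cAMP"):
        network_rhs(0.0, y, params, proto)


def test_negligible_amplitude_leaves_cam_at_basal_equilibrium(params):
    proto = make_protocol("LFS", amplitude=1e-12, n_pulses=3)
    r = integrate(params, proto)
    start = r.y[:9, 0]
    dev = np.abs(r.y[:9] - start[:, None]).max()
    assert dev < 1e-3 * params.CaM_T


def test_hz100_converts_cam_pool_to_cam4(sim, params):
    r = sim("HZ100")
    end = observables(r, "CaM4_total", "end_of_train")
    assert end > 0.9 * params.CaM_T


def test_lfs_bound_species_dissociate_between_pulses(sim):
    """At 1 Hz each bound CaM target loses most of its CaM before the next
    pulse (off-rates ~1 s⁻¹ against a 1 s inter-pulse interval)."""
    r = sim("LFS")
    t_pulse = r.protocol.pulse_times[20]
    before = np.argmin(np.abs(r.t - (t_pulse - 0.01)))
    early = np.argmin(np.abs(r.t - (t_pulse + 0.05)))
    late = np.argmin(np.abs(r.t - (t_pulse + 0.95)))
    for name in ("CaMAC1", "CaMAC8", "CaMPDE1", "CaMCaMKII"):
        s = r.series(name)
        gained = s[early] - s[before]          # CaM picked up from this pulse
        retained = s[late] - s[before]
        assert gained > 0, name
        assert retained < 0.5 * gained, name


def test_observables_identities(sim, params):
    r = sim("HZ100")
    assert r.series("I1PP1")[0] == 0.0
    for which in ("CaM4_total", "cAMP", "I1PP1"):
        peak = observables(r, which, "peak")
        end = observables(r, which, "end_of_train")
        avg = observables(r, which, "time_average")
        assert peak >= end >= 0.0
        assert peak >= avg >= 0.0
    # all CaM in complexes sums to the total pool
    w = r.train_window
    total = r.series("CaM4_total") + r.y[:8].sum(axis=0)
    assert np.allclose(total, params.CaM_T, rtol=1e-9)
    with pytest.raises(ValueError):
        observables(r, "pT286")
    with pytest.raises(ValueError):
        observables(r, "cAMP", "median")


def test_integrate_rejects_bad_arguments(params):
    proto = make_protocol("HZ10")
    with pytest.raises(ValueError):
        integrate(params, proto, mode="hybrid")
    with pytest.raises(ValueError):
        integrate(params, proto, t_end=0.5 * proto.train_end)


def test_integration_is_deterministic(params):
    proto = make_protocol("HZ10")
    r1 = integrate(params, proto)
    r2 = integrate(params, proto)
    assert np.array_equal(r1.t, r2.t)
    assert np.array_equal(r1.y, r2.y)


def test_derived_series_recomputable(sim):
    r = sim("HZ100")
    a = r.series("CaM4_total")
    b = r.y[CAM4] + sum(r.y[IDX[n]] for n in CAM_BOUND)
    assert np.array_equal(a, b)
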