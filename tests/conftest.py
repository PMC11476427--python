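import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_cfl_warnings():
    # coarse test meshes legitimately trip the advective-CFL advisory
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="advective CFL")
        yield


@pytest.fixture(scope="session")
def channel():
    """Coarse plane channel with a steady Poiseuille solution."""
    from carotidrisk import boundary_conditions as bc
    from carotidrisk import flow_sim as fs

    length, height = 0.02, 4e-3
    mesh = fs.straight_channel_mesh(length, height, 0.8e-3)
    props = bc.FluidProps()
    mean_u = 0.2
    v, p, space = fs.solve_steady(
        mesh, fs.DirichletBC("inlet", props.density * mean_u * height), props=props
    )
    return dict(mesh=mesh, v=v, p=p, space=space, props=props,
                mean_u=mean_u, height=height, length=length)


@pytest.fixture(scope="session")
def small_transient():
    """Low-Reynolds pulsatile bifurcation run on a coarse mesh (fast)."""
    from carotidrisk import boundary_conditions as bc
    from carotidrisk import flow_sim as fs
    from carotidrisk import synth_data as sd

    geom = sd.generate_geometry(stenosis_severity=0.4, seed=2)
    mesh = fs.mesh_domain(geom, h_max=2.0e-3)
    props = bc.FluidProps()
    period = 0.9
    wave = bc.velocity_waveform(0.35, 0.12, period)
    m_cca = bc.mass_flow_waveform(wave, geom.widths["cca"], props)
    m_eca = bc.mass_flow_waveform(wave, geom.widths["eca"], props)
    sol = fs.solve_transient(
        mesh,
        fs.DirichletBC("inlet", m_cca),
        fs.DirichletBC("outlet_eca", m_eca, outflow=True),
        props,
        dt=period / 30,
        n_cycles=3,
    )
    return dict(geom=geom, mesh=mesh, sol=sol, props=props, period=period)


@pytest.fixture(scope="session")
def cohort_134():
    from carotidrisk import synth_data as sd

    return sd.generate_cohort(sd.GenerativeRiskSpec(seed=7))


@pytest.fixture(scope="session")
def small_gbt():
    """Small boosted model on 8 informative features for attribution tests."""
    from carotidrisk import risk_model as rm

    rng = np.random.default_rng(5)
    n, p = 120, 8
    X = rng.standard_normal((n, p))
    y = (X[:, 0] + 0.6 * X[:, 1] - 0.8 * X[:, 2] + 0.3 * rng.standard_normal(n) > 0)
    cols = [rm.ColumnMeta(f"f{i}", "other", False) for i in range(p)]
    fm = rm.FeatureMatrix(X, cols, y.astype(int))
    model = rm.gbt_fit(fm, n_estimators=30)
    return dict(model=model, X=X, y=y.astype(int), fm=fm)
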