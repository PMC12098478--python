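"""Shared helper: a constant-volume model with homogeneous rates, used to
check the simulator against textbook Poisson/exponential laws."""

from oncotraj.models import ModelSpec

_NAMES = ("beta", "m_basal", "m_size", "d_size", "d_metas")


def flat_model(m_basal=0.0, d_metas=0.0, d_size=0.0) -> ModelSpec:
    return ModelSpec(
        name="flat",
        growth_law="exponential",
        metastasis_kind="volume",
        free_names=_NAMES,
        log_bounds={n: (-20.0, 2.0) for n in _NAMES},
        true_theta={
            "beta": 1e-12,
            "m_basal": m_basal,
            "m_size": 1e-30,
            "d_size": d_size,
            "d_metas": d_metas,
        },
        fixed={"S0": 1.0, "S_cell": 1e-7, "sigma_S": 0.1, "N0": 0},
    )
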