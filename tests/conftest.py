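import numpy as np
import pytest

import moltenfit as mf

# Published thermodynamic parameters of the HCAII Pro237 panel used as
# generating truth throughout: variant -> (dG_NI, m_NI, dG_IU, m_IU).
PANEL_THERMO = {
    "HCAII_pwt":   (5.7, 6.3, 7.8, 3.9),
    "HCAII_P237A": (6.5, 6.5, 6.0, 2.8),
    "HCAII_P237T": (4.7, 5.2, 6.4, 3.0),
    "HCAII_P237N": (5.0, 5.5, 7.3, 3.6),
    "HCAII_P237I": (5.1, 6.2, 7.5, 3.7),
    "HCAII_P237F": (5.3, 6.3, 5.3, 2.5),
}

# Published dG_NU / ddG_NU columns (kcal/mol); P237H is literature-only.
DG_NU = {"HCAII_pwt": 13.5, "HCAII_P237A": 12.5, "HCAII_P237T": 11.1,
         "HCAII_P237N": 12.3, "HCAII_P237I": 12.6, "HCAII_P237F": 10.6}
DDG_NU = {"HCAII_pwt": 0.0, "HCAII_P237A": 1.0, "HCAII_P237T": 2.4,
          "HCAII_P237N": 1.2, "HCAII_P237I": 0.9, "HCAII_P237F": 2.9}
P237H_LITERATURE_DDG = 7.3


@pytest.fixture(scope="session")
def pwt_params() -> mf.ThreeStateParams:
    dg_ni, m_ni, dg_iu, m_iu = PANEL_THERMO["HCAII_pwt"]
    return mf.ThreeStateParams(
        ni=mf.TransitionThermo(dg_ni, m_ni),
        iu=mf.TransitionThermo(dg_iu, m_iu),
        baseline_n=336.0, baseline_i=341.0, baseline_u=355.0)


@pytest.fixture(scope="session")
def panel() -> mf.PanelSpec:
    return mf.hcaii_panel()


@pytest.fixture(scope="session")
def pwt_noiseless_curve(pwt_params) -> mf.DenaturationCurve:
    return mf.generate_curve(pwt_params, noise_sd=0.0, sample_id="HCAII_pwt")
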