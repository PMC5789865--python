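import numpy as np
import pytest

from poprisk import DiseasePanel, SnpMarker


def make_marker(rsid="rs1", orx=1.5, p=1e-9, **kw):
    defaults = dict(
        risk_allele="G", other_allele="A", or_per_allele=orx, p_discovery=p,
        study_type="gwas_discovery", n_cases=2000, n_controls=2000,
    )
    defaults.update(kw)
    return SnpMarker(rsid=rsid, **defaults)


@pytest.fixture
def small_panel():
    """Three-marker panel with known odds ratios and discovery frequencies."""
    markers = [
        make_marker("rs1", orx=1.3, risk_allele_freq={"discovery": 0.30}),
        make_marker("rs2", orx=1.6, risk_allele_freq={"discovery": 0.50}),
        make_marker("rs3", orx=0.8, risk_allele_freq={"discovery": 0.20}),
    ]
    return DiseasePanel(disease_name="trait", markers=markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
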