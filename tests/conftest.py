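import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_pipeline():
    """Noiseless control scenario run through subtract -> baseline ->
    normalize -> fit on both windows, with the generator truth attached."""
    import warnings

    import emfbio as eb
    from emfbio.peaks import WINDOW_HIGH, WINDOW_LOW, fit_region
    from emfbio.preprocess import normalize_total, remove_baseline, subtract_background
    from emfbio.synthetic import SpectrumScenario

    scn = SpectrumScenario(noise_sd=0.0, cell_variability_cv=0.0, seed=11)
    rng = np.random.default_rng(11)
    cell, truth = eb.generate_cell_spectrum(scn, rng, return_truth=True)
    bg = eb.generate_background_spectrum(scn, rng)
    debased, diag = remove_baseline(subtract_background(cell, bg))
    total = debased.total_intensity()
    norm = normalize_total(debased)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_low = fit_region(norm, WINDOW_LOW)
        fit_high = fit_region(norm, WINDOW_HIGH)
    return {
        "scenario": scn, "cell": cell, "background": bg,
        "normalized": norm, "total": total, "truth": truth,
        "baseline_diag": diag, "fit_low": fit_low, "fit_high": fit_high,
    }
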