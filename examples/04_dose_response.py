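"""Oocyte dose-response analysis: amplitudes, normalization, EC50.

Simulates voltage-clamp current traces for a receptor with the
ClOr1/Orco-nonanal EC50 (5.186e-7 M) over six decadic doses, extracts
peak amplitudes, normalizes to a 0-100 scale, fits the Hill equation and
reports EC50 with its confidence interval plus a response-threshold dose.
"""

import numpy as np

import cimexolf as co

true_ec50 = 5.186e-7  # M
doses = 10.0 ** np.arange(-9.0, -3.0)

traces = co.gen_current_trace(
    ec50=true_ec50, hill=1.0, emax=800.0, doses=doses,
    noise_sd=16.0, seed=4,
)
amplitudes = np.array([co.extract_amplitude(t) for t in traces])
print("peak currents (nA):", amplitudes.round(1))

normalized = co.normalize_series(amplitudes, mode="max_is_100")
series = co.DoseResponseSeries(
    doses, normalized, ligand="nonanal", receptor="ClOr1/Orco"
)
fit = co.fit_hill(series)
lo, hi = fit.ec50_ci
print(
    f"fitted EC50 = {fit.ec50:.3e} M (true {true_ec50:.3e}), "
    f"95% CI [{lo:.2e}, {hi:.2e}], hill n = {fit.hill_n:.2f}"
)

threshold = co.threshold_dose(fit, fraction_of_emax=0.1, dose_grid=doses)
print(
    f"10%-of-Emax threshold dose: {threshold.dose:.2e} M "
    f"(lowest tested dose reaching it: {threshold.grid_dose:.0e} M)"
)
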