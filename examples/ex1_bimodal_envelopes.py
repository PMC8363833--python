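"""Bimodal envelope fitting and EX1/EX2 classification.

Simulates an isotope-envelope time course for a peptide inside an EX1
region: a strongly protected (folded) population coexists with an
unfolded population that appears at the opening rate k_open and
exchanges fully.  Each envelope is fitted with one- and two-component
mixtures; corrected-AIC model selection with a resolvability guard picks
the bimodal model only when two populations are genuinely present.
"""

from hdxflex import HDXSimConfig, PeptideRecord, classify_ex1_ex2, fit_bimodal
from hdxflex.synthetic import heavy_fraction, simulate_peptide_uptake_ex1

SEQ = "AKLMNQRSTVWYAGHIDEFKLV"
PEP = PeptideRecord(SEQ[:12], 1, 12)
EXPOSURES = (60.0, 600.0, 3600.0, 10000.0)
K_OPEN = 3e-4  # /s

cfg = HDXSimConfig(
    protein_sequence=SEQ,
    protection_factor=1e5,              # folded population barely exchanges
    ex1_regions=[(1, 12, K_OPEN)],
    back_exchange_fraction=0.0,
    exposures=EXPOSURES,
    envelope_snr=50.0,
    seed=0,
)

fits = []
print("exposure   true f_heavy   fitted model        fitted f_heavy")
for t in EXPOSURES:
    env = simulate_peptide_uptake_ex1(cfg, PEP, t)
    fit = fit_bimodal(env)
    fits.append(fit)
    model = "bimodal" if fit.preferred else "unimodal"
    print(f"{t:7.0f} s   {heavy_fraction(K_OPEN, t):11.3f}   "
          f"{model:18s} {fit.fraction_heavy:.3f}")

label = classify_ex1_ex2(fits, EXPOSURES)
print(f"\ntime-course classification: {label}")
print(
    "The heavy-population fraction grows as 1 - exp(-k_open t) while both\n"
    "component centroids stay put -- the signature of EX1 kinetics.  (A\n"
    "single drifting centroid would classify as EX2.)"
)
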