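"""Pooled titer estimation from a dilution series, with exact Poisson CIs.

A sample is plated at several volumes and decimal dilutions; plaque counts
are pooled as a Poisson maximum-likelihood estimate (total plaques over
total effective volume) with a Garwood chi-square confidence interval.
"""

from pdptools import CountObservation, final_concentration, moi, titer_from_counts

# three replicates x volumes 10/100/500 uL at dilutions 10^0..10^-2 of a
# sample whose true concentration is about 1000 PFU/mL
counts = [
    CountObservation(count=c, plated_volume_ml=v, dilution_exponent=d)
    for c, v, d in [
        (12, 0.010, 0), (1, 0.010, 1), (0, 0.010, 2),
        (104, 0.100, 0), (9, 0.100, 1), (2, 0.100, 2),
        (488, 0.500, 0), (53, 0.500, 1), (4, 0.500, 2),
    ]
]
est = titer_from_counts(counts, alpha=0.05)
print(
    f"titer {est.titer:.0f} PFU/mL, 95% CI [{est.ci_lower:.0f}, {est.ci_upper:.0f}]\n"
    f"({est.total_count} plaques pooled over {est.effective_volume_ml:.3f} mL "
    f"effective volume; plates outside the 3-300 countable range were dropped)"
)

# assay arithmetic: mixing 50 uL of phage at 1e6 PFU/mL with 50 uL of cells
# at 1e8 CFU/mL, and dosing 20 uL of a 1e7 PFU/mL stock into a 200 uL well
print(f"adsorption-assay MOI = {moi(0.050, 1e6, 0.050, 1e8):g} phage per cell")
print(f"well concentration  = {final_concentration(1e7, 0.020, 0.200):g} PFU/mL")
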