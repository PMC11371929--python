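"""Genome-phenotype scoring: HRD probability and MSI calling.

Simulates one homologous-recombination-deficient prostate tumor and one
microsatellite-unstable stomach tumor next to matched proficient/stable
controls, and prints the phenotype scores that separate them.
"""

from oncointerp import SimulationConfig, run_sample, simulate_callset

for label, cfg in [
        ("HRD-deficient prostate", SimulationConfig(seed=1, hrd_status=True,
                                                    cancer_type="prostate")),
        ("HR-proficient prostate", SimulationConfig(seed=2, hrd_status=False,
                                                    cancer_type="prostate")),
        ("MSI-H stomach", SimulationConfig(seed=3, msi_status="MSI-H",
                                           cancer_type="stomach")),
        ("MSS stomach", SimulationConfig(seed=4, msi_status="MSS",
                                         cancer_type="stomach"))]:
    report = run_sample(*simulate_callset(cfg)[:5])
    p = report.phenotypes
    print(f"{label}:")
    print(f"  HRD probability {p.hrd_probability:.3f} "
          f"({'positive' if p.hrd_positive else 'negative'} at the 0.7 cutoff)")
    print(f"  MSI site score {p.msisensor_like_score:.1f}%, "
          f"MSI signature proportion {p.msi_signature_proportion:.2f} "
          f"-> {p.msi_call}")
# HRD probability combines SBS3/SBS8, ID6, RS3/RS5 exposures, microhomology
# deletions and long LOH segments; MSI is called when either the site-level
# instability score (>= 3.5) or the MSI signature proportion (>= 0.20) fires.
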