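"""Simulate one tumor/normal call set and interpret it end to end.

Generates a lung adenocarcinoma-like sample carrying an EGFR L858R point
driver, then runs filtering, signature refitting, phenotyping, driver calling
and category assignment, printing the headline results.
"""

from oncointerp import DriverSpec, SimulationConfig, run_sample, simulate_callset

config = SimulationConfig(
    seed=11, sample_id="EXAMPLE-01", cancer_type="lung",
    drivers=[DriverSpec("EGFR", "point", "L858R", "missense")])

variants, svs, profile, germline, sites, truth = simulate_callset(config)
report = run_sample(variants, svs, profile, germline, sites)

print(f"sample {report.sample_id} ({report.cancer_type})")
print(f"  records: {len(variants)} SNV/indel calls, {len(svs)} SVs, "
      f"{len(profile.segments)} CN segments")
print(f"  TCF {report.tcf:.0%}, ploidy {report.ploidy:.1f}, "
      f"interpretable: {report.interpretable}")
p = report.phenotypes
print(f"  TMB {p.tmb:.2f}/Mb | WGD {p.wgd} | HRD p={p.hrd_probability:.3f} "
      f"| MSI {p.msi_call}")
for d in report.drivers:
    print(f"  driver: {d.gene} {d.alteration} [{d.driver_class}] "
          f"evidence={d.evidence}")
print(f"  category: {report.category.category}  "
      f"(evidence: {report.category.evidence})")
# The category I-1 line means an approved therapy (erlotinib) matches the
# EGFR L858R driver in a lung cancer; TMB is mutations per callable megabase.
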