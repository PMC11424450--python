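"""Test whether two traits share a causal variant in a region.

Simulates a 100-SNP region where gene expression and disease risk are
driven by the same causal SNP (the colocalizing case), then by two
distinct SNPs, and prints the posterior over the five hypotheses
H0 (no signal) ... H4 (shared variant).
"""

from mrscreen import (ColocSimConfig, coloc_abf, declare_colocalized,
                      simulate_coloc_region)

for scenario in ("h4", "h3", "h0"):
    r1, r2, truth = simulate_coloc_region(
        ColocSimConfig(m_snps=100, scenario=scenario, causal_z=8.0, seed=5))
    res = coloc_abf(r1, r2)
    pp = " ".join(f"{k.split('.')[1]}={v:.3f}" for k, v in res.pp.items())
    print(f"simulated {scenario}: {pp}")
    if scenario == "h4":
        print(f"  colocalized (PP.H4 > 0.80): "
              f"{declare_colocalized(res)}; "
              f"top shared SNP {res.top_shared_snp} "
              f"(truth: {truth['causal_trait1']})")

print("\nA shared causal variant concentrates posterior mass on H4 and the "
      "per-SNP attribution points at the right SNP; distinct variants land "
      "on H3; a flat region lands on H0.")
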