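"""Generate the default synthetic multi-arm study and look at its structure.

The generator emulates a 14-group mouse dyslipidemia trial: a low-fat-diet
baseline (LFD), a 9-week high-fat time point, untreated high-fat disease,
a dietary intervention (DLI) and ten drug arms, 8 animals each, with liver
expression for all groups, adipose expression for a 7-group subset, 26
physiological markers and a metabolite panel — all coupled through a
latent per-animal disease load.
"""

from devindex import default_study_config, generate

study = generate(default_study_config(seed=42))

for tissue, mat in study.expression.items():
    print(f"{tissue} expression: {mat.shape[0]} samples x {mat.shape[1]} probes")
print(f"markers: {study.markers.shape}, metabolites: {study.metabolites.shape}")

print("\nplanted disease load per group (0 = healthy baseline, 1 = untreated disease):")
for g, load in study.truth.group_loads.items():
    print(f"  {g:<14} {load:.2f}")

print("\nplanted overshoots (marker pushed past the disease state):")
for marker, group, shift in study.truth.overshoot_plants:
    print(f"  {marker} in {group} (+{shift:.2f})")
# Each animal's realized load jitters around its group's planted value;
# every downstream analysis tries to recover this hidden structure.
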