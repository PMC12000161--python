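"""Detect planted teeth and gullets with the 12-contrast battery.

Simulates three 20-individual cohorts — featureless, one with a tooth
(peak) planted at station 5, one with a gullet there — applies the
contrast battery to the slope angles, and prints each species' calls.
"""

from chelamorph import SpeciesTemplate, battery_table, generate_community, species_summary

noise = 1.5  # within-cohort station noise SD, µm
templates = [
    SpeciesTemplate(label="flat", plateau_depth=0, basal_height=0, noise_sd=noise),
    SpeciesTemplate(label="toothy", plateau_depth=0, basal_height=0, noise_sd=noise,
                    modules=((5.0, 3 * noise, 0.7),)),
    SpeciesTemplate(label="gulleted", plateau_depth=0, basal_height=0, noise_sd=noise,
                    modules=((5.0, -3 * noise, 0.7),)),
]
community = generate_community(templates, seed=42)
profiles = [p for cohort, _ in community.cohorts.values() for p in cohort]

table = species_summary(battery_table(profiles))
print(table.species[["taxon", "contrast", "centre", "mean", "band", "call"]]
      .round(2).to_string(index=False))
print()
print("A mean below -band is an apparent peak (tooth), above +band an")
print("apparent gullet. The planted features surface at contrast c3, the")
print("atomic second-difference contrast centred at station 5.")
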