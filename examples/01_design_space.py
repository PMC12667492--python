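"""Enumerate the synthesis space and turn a recipe into a pipetting plan.

The screening space spans [Ca2+] 2–98 mM, [IDC ligand] 22.5–122.5 mM, and
[enzyme] 0.2–1.96 mg/mL on a 17 x 101 x 103 grid (176,851 combinations).
"""

from enzymof import Recipe, StockSet, default_grid, recipe_to_volumes, volumes_to_recipe

grid = default_grid()
print(f"synthesis space: {grid.size} candidate recipes")
for ax in grid.axes:
    print(f"  {ax.name}: {ax.minimum}–{ax.maximum} in {ax.n_levels} levels (step {ax.step:.5g})")

# A bench-scale recipe: 50.8 mM Ca, 18.25 mM ligand, 0.2 mg/mL enzyme in 500 µL.
stocks = StockSet()  # 100 mM Ca, 125 mM ligand, 2 mg/mL enzyme stocks
recipe = Recipe(ca_conc=50.8, idc_conc=18.25, enzyme_conc=0.2)
plan = recipe_to_volumes(recipe, stocks)
print(f"\npipetting plan for {recipe}:")
print(f"  water {plan.water_vol} µL, ligand {plan.idc_vol} µL, "
      f"enzyme {plan.enzyme_vol} µL, Ca {plan.ca_vol} µL (total {plan.total} µL)")

back = volumes_to_recipe(plan, stocks)
print(f"round-trip recipe: {back}")
# The integer-µL rounding bounds each recovered concentration within
# half a pipetting increment of the requested one.
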