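"""From tree measurements to plot biomass.

Builds one fixed-radius and one prism (variable-radius) plot, applies
the species-group allometry AGB = exp(b0 + b1 ln DBH) to each tree,
expands trees to per-acre counts, and prints the plot AGB in Mg/ha.
"""

from agbkrige import PlotRecord, TreeRecord, expansion_factor, plot_agb_mg_ha, tree_agb_kg

frp = PlotRecord("frp-1", 0, 0, "FRP", area_fraction_acre=1 / 25, trees=[
    TreeRecord("Pine", 25.4),
    TreeRecord("Pine", 18.0),
    TreeRecord("SH", 31.0),
])
vrp = PlotRecord("vrp-1", 0, 0, "VRP", baf=10.0, trees=[
    TreeRecord("Pine", 25.4),
    TreeRecord("HH", 40.0),
])

for plot in (frp, vrp):
    print(f"plot {plot.plot_id} ({plot.plot_type}):")
    for tree in plot.trees:
        kg = tree_agb_kg(tree.species_group, tree.dbh_cm)
        tpa = expansion_factor(plot, tree)
        print(f"  {tree.species_group:4s} DBH {tree.dbh_cm:5.1f} cm -> "
              f"{kg:7.1f} kg/tree x {tpa:7.2f} trees/acre")
    print(f"  plot AGB = {plot_agb_mg_ha(plot):.2f} Mg/ha")

# A 25.4 cm (10 in) pine weighs ~209 kg; on a 1/25-acre plot it stands
# for 25 trees/acre, in a BAF-10 prism plot for ~18.3 trees/acre. The
# plot totals are those per-acre masses converted to Mg/ha.
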