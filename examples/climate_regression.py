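"""Regress regulon size on source-habitat minimum temperature.

Colder collection sites are associated with larger cold regulons; with
three genotypes the fit is descriptive (small-n caveat), reporting slope
and R^2 only.
"""

from cbfreg import fit_count_vs_temperature
from cbfreg.simulate import default_climate_panel

panel = default_climate_panel()
print(panel.to_string(index=False))

for response in ("regulon_count", "cor_count"):
    fit = fit_count_vs_temperature(panel, response)
    caveat = " [small n: descriptive only]" if fit.small_n_caveat else ""
    print(f"\n{response}: slope = {fit.slope:.1f} genes/degC, "
          f"intercept = {fit.intercept:.0f}, R^2 = {fit.r_squared:.3f}"
          f"{caveat}")
print("\nA negative slope means genotypes from colder habitats deploy "
      "more cold-regulated genes.")
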