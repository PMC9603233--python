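"""Wall-spraying of an aqueous hydrogen peroxide disinfectant.

Builds the packaged reference scenario — 7.4% w/w H2O2 sprayed for 5 min
onto a 20 m^2 wall of a 150 m^3 animal housing — runs the full mass-balance
simulation and prints the exposure summary.
"""

from spraymix import mass_audit, run
from spraymix.fixtures import worked_example_h2o2
from spraymix.spray_source import critical_diameter

sc = worked_example_h2o2()
rho = sc.product_density()
d_crit = critical_diameter(sc.jet, rho, sc.env)
print(f"product density           {rho:7.1f} kg/m^3")
print(f"impaction critical diam.  {d_crit * 1e6:7.1f} um "
      "(larger droplets deposit on the wall)")

result = run(sc, record_every=4)
frame = result.frame

peak_aerosol = frame["A_inh"].max() * 1e6
peak_vapour = frame["C_H2O2"].max() * 1e6
t_peak = frame.loc[frame["C_H2O2"].idxmax(), "t"]
twa_spray = result.twa("A_inh_H2O2", (0.0, 300.0)) * 1e6
twa_vapour = result.twa("C_H2O2") * 1e6

print(f"peak inhalable aerosol    {peak_aerosol:7.1f} mg/m^3 (during spraying)")
print(f"spray-phase H2O2 aerosol  {twa_spray:7.2f} mg/m^3 (5-min TWA)")
print(f"peak H2O2 vapour          {peak_vapour:7.1f} mg/m^3 at t = {t_peak / 60:.0f} min")
print(f"5-h H2O2 vapour TWA       {twa_vapour:7.1f} mg/m^3")

audit = mass_audit(result)
print(f"mass released             {audit['released'] * 1e3:7.1f} g "
      f"({audit['released_wall'] * 1e3:.0f} g onto the wall)")
print(f"ledger closure error      {audit['closure_error']:.2e}")
print()
print("The aerosol peak is confined to the 5-min spraying phase; the vapour")
print("peak arrives ~1 h later, fed by evaporation from the wall and floor")
print("films and delayed by the water vapour backpressure in the room air.")
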