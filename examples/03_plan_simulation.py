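"""Plan the simulation artifacts for an alchemical PTM study.

Generates (as text only) the two-stage lambda schedule, an equilibration
protocol with SLTCAP ion counts, a multi-ligand docking configuration and
a scheduler batch script.
"""

from ptmforge.fixtures import make_toy_protein
from ptmforge.solvation import sltcap_ion_counts
from ptmforge.workflow import (gen_batch_script, gen_docking_config,
                               gen_equilibration_protocol, gen_ti_schedule)

schedule = gen_ti_schedule()
print(f"lambda schedule: {len(schedule.stages)} stages x "
      f"{len(schedule.stages[0][1])} lambda values = {len(schedule.legs)} legs "
      f"of {schedule.leg_duration_ns:g} ns (the coupled endpoint is shared)")

protein = make_toy_protein(5, ["ALA", "CYS", "SER", "GLY", "ALA"])
protocol, script = gen_equilibration_protocol(protein, protein_charge=-4)
print(f"equilibration: ladder {protocol.minimization_ladder} kJ/mol/nm^2, "
      f"{protocol.nvt_ps:g} ps NVT, {protocol.npt_ns:g} ns unrestrained NPT")
print(f"ions: {protocol.n_cations} cations / {protocol.n_anions} anions "
      "(exact charge neutralization at 0.15 mol/L)")

plan = sltcap_ion_counts(-8, 0.15, 1000.0)
print(f"SLTCAP for Q=-8e in 1000 nm^3 water: "
      f"{plan.n_cations}+ / {plan.n_anions}-")

config, text = gen_docking_config("receptor.pdbqt",
                                  ["ga3p.pdbqt", "nadp.pdbqt"],
                                  box=((10.0, 5.0, 2.0), (10.0, 10.0, 10.0)))
print(f"docking: exhaustiveness {config.exhaustiveness}, box {config.size} A "
      "(clamped to hold both ligands)")

print("\nbatch script:")
print(gen_batch_script(script, partition="shared"))
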