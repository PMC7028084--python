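"""The closed-form assay computations on small worked inputs.

Cortical tension by the law of Laplace on a synthetic aspiration table
(ground-truth round trip), the specific cytotoxic index anchored at the
4.51% spontaneous-death control, homing indices, and the adhesion-frequency
cohort summary.
"""

from blebkit.assays import (
    AdhesionTrialSet,
    AspirationMeasurement,
    HomingRecord,
    KillingAssayRecord,
    adhesion_frequency,
    cortical_tension,
    homing_indices,
    specific_cytotoxic_index,
)
from blebkit.simulate import simulate_aspiration, simulate_killing_assay

# Laplace: Tc = Rc*Rp / (2 (Rc - Rp)) * dp  (um, Pa -> pN/um)
m = AspirationMeasurement(Rp_um=2.0, Rc_um=4.0, dp_Pa=100.0, Lp_um=2.0)
print(f"cortical tension: {cortical_tension(m).Tc_pN_um:.0f} pN/um "
      f"(hand value 200)")
rec = simulate_aspiration(1, seed=0)[0]
got = cortical_tension(rec.measurement).Tc_pN_um
print(f"round trip: true {rec.true_Tc_pN_um:.3f}, recovered {got:.3f} pN/um")

# killing assay: index anchored at the 4.51% spontaneous-death control
r = KillingAssayRecord(experimental_death_pct=40.0, spontaneous_death_pct=4.51,
                       maximum_death_pct=80.0)
index, flagged = specific_cytotoxic_index(r)
print(f"specific cytotoxic index: {index:.2f}% (flagged: {flagged})")
print(simulate_killing_assay(4.51, 80.0, [0.0, 50.0, 100.0]).to_string(index=False))

# homing: tissue fraction over input and over day-6 blood
hi, norm = homing_indices(HomingRecord(pct_mcherry_tissue=10.0,
                                       pct_mcherry_input=20.0,
                                       pct_mcherry_blood_day6=5.0))
print(f"homing index {hi:.2f}, blood-normalized {norm:.2f}")

# adhesion frequency over 10-touch pairs
trials = [
    AdhesionTrialSet("pair1", (1, 1, 1, 0, 1, 0, 1, 1, 0, 1)),
    AdhesionTrialSet("pair2", (0, 1, 0, 0, 1, 0, 0, 1, 0, 0)),
    AdhesionTrialSet("pair3", (1, 1, 1, 1, 1, 1, 0, 1, 1, 1)),
]
per_pair, summary = adhesion_frequency(trials)
print(f"adhesion frequencies: {per_pair}")
print(f"cohort median {summary['median']:.2f}, "
      f"IQR [{summary['q1']:.2f}, {summary['q3']:.2f}]")
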