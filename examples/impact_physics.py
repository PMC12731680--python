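"""Slider-impact kinematics and the crack-severity map.

A 150 g slider released from 10-15 cm on a smooth incline produces the
impact energies used to crack the eggs; severity saturates with energy.
"""

from crackspec import ImpactModel, impact_kinematics, severity_from_energy

for height_cm in (10, 12.5, 15):
    model = ImpactModel(mass_kg=0.150, height_m=height_cm / 100)
    velocity, energy = impact_kinematics(model)
    severity = severity_from_energy(energy)
    print(f"release {height_cm:5.1f} cm -> impact {velocity:.2f} m/s, "
          f"{energy:.3f} J, severity {severity:.2f}")

# The printed velocities span ~1.40-1.71 m/s and energies ~0.15-0.22 J;
# severity (crack extent, 0..1) grows monotonically but saturates, so
# doubling the drop height does not double the damage.
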