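"""Discharge-regime staircase of the integer-order Hindmarsh-Rose neuron.

Sweeps the stimulation current through the canonical values and prints
the classified regime: the period-adding route from slow spiking through
period-2/3/4 bursting into chaos and back to fast spiking.
"""

from fohrlearn import HRParameters
from fohrlearn.experiments import regime_table

table = regime_table([1.5, 1.8, 2.3, 2.8, 3.2, 3.58], q=1.0, duration=4000.0)
print("I      regime")
for I, label in table.items():
    print(f"{I:<6g} {label}")
print()
print("Each 'period-n bursting' line means n spikes cluster per burst;")
print("the chaotic call marks an irregular inter-spike-interval sequence.")
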