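"""Generate a small synthetic cohort and look at what one recording contains.

The generator emulates a posed-expression protocol recorded by smart glasses
with six 3-axis optical skin-displacement (OMG) sensors at 50 Hz: three tasks
(intensity/duration grid, head movement, glasses position), four expressions
plus neutral rest, three repetitions per condition.
"""

import numpy as np

from omgpipe import generate_cohort, vocab

cohort = generate_cohort(n_participants=3, seed=42)
rec = cohort[0]

print(f"participants: {len(cohort)}")
print(f"recording {rec.participant_id}: {rec.n_samples} samples "
      f"({rec.n_samples / rec.sampling_rate_hz / 60:.1f} min at {rec.sampling_rate_hz:.0f} Hz)")
print(f"streams: {len(rec.data.columns)} ({', '.join(list(rec.data.columns[:3]))}, ...)")
print(f"events: {len(rec.events)} "
      f"({len(rec.events) // len(vocab.EXPRESSIONS)} per expression)")

smile = next(e for e in rec.events if e.expression == "smile" and e.intensity == "high")
cheek = np.sqrt((rec.site_xyz("cheek_left") ** 2).sum(axis=1))
plateau = cheek[smile.start : smile.end].max()
print(f"\nfirst high-intensity smile: samples [{smile.start}, {smile.end}), "
      f"peak left-cheek displacement {plateau:.1f} mm")
print("Displacements are in millimetres of skin movement over the zygomaticus "
      "(cheek), frontalis/corrugator (brow) and temple sites.")
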