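"""Three-phase SFDI vs single-snapshot (SSOP) demodulation.

Renders noiseless structured-illumination frames of a four-region
perfusion phantom and compares the modulation amplitudes recovered from
three phase-shifted frames (exact) and from a single frame via Fourier
filtering (fast, with edge artifacts).
"""

import numpy as np

from ssopkit import make_phantom, render_frames
from ssopkit.demodulation import (
    THREE_PHASES,
    demodulate_ssop,
    demodulate_three_phase,
    fx_to_cycles_per_pixel,
)

scene = make_phantom("four_roi")
w = scene.wavelengths[0]
acq3 = render_frames(scene, (0.2,), THREE_PHASES)   # 3 frames
acq1 = render_frames(scene, (0.2,), (0.0,))         # 1 frame

m3 = demodulate_three_phase(*acq3.stacks[w].frames)
err3 = np.max(np.abs(m3.m_ac - acq3.truth[w]["m_ac"]) / acq3.truth[w]["m_ac"])
print(f"three-phase: max |M_AC - truth|/truth = {err3:.2e} (exact identity)")

k0 = fx_to_cycles_per_pixel(0.2, scene.pixel_pitch)
m1 = demodulate_ssop(acq1.stacks[w].frames[0], k0)
m = m1.edge_margin
rel = np.abs(m1.m_ac - m3.m_ac)[:, m:-m] / m3.m_ac[:, m:-m]
print(f"SSOP:        edge margin = {m} px; "
      f"median interior |SSOP - SFDI|/SFDI = {np.median(rel):.2e}")
print("-> one frame instead of three costs a border margin and ringing "
      "near property edges, but the interior agrees to a fraction of a "
      "percent.")
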