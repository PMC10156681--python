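"""Replay the chroma-selection rule on the observed variance continuum.

Ten blue-channel variances spanning the red-to-pale continuum are pushed
through the θ=1500 rule; the first five (red-dominant) must select the a*
plane, the last five the b* plane.
"""

from retilume import select_chroma_channel

OBSERVED = [91.77, 121.17, 598.96, 692.87, 977.61, 1868.32, 2199.51, 3213.49, 4262.72, 4404.08]

for sigma_sq in OBSERVED:
    result = select_chroma_channel(sigma_sq, theta=1500.0)
    print(
        f"sigma^2 = {sigma_sq:8.2f}  ->  {result.dominance_label:<16s}  "
        f"enhance {result.selected_channel}"
    )

print()
print("a* (red-green axis) is enhanced for red-dominant images, b* (yellow-blue)")
print("for pale ones, so CLAHE always works on the chroma plane carrying the signal.")
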