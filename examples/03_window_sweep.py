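"""Sweeping the smoothing window W to find the family-optimal width W*.

On a record whose peaks are planted with zero spread in 13-residue
motifs, every window up to the motif width sees a perfectly level peak
set; wider windows mix in background and the statistic degrades.  W* is
the deviation minimizer, ties toward the smaller window.
"""

from hydrolevel import SyntheticSpec, generate, load_scale, window_sweep

mz = load_scale("MZ")
record, _ = generate(SyntheticSpec(length=420, motif_width=13,
                                   min_spacing=50, level_spread=0.0, seed=11))

result = window_sweep(record, mz, windows=range(9, 22, 2), k=5)
print("window  deviation  n_peaks")
for w in sorted(result.per_window):
    _, stat = result.per_window[w]
    if stat is None:
        print(f"{w:6d}  (no scorable peak set)")
    else:
        print(f"{w:6d}  {stat.deviation:9.4f}  {stat.n_peaks:7d}")
print(f"\nW* = {result.best_window} "
      f"(deviation {result.best_stat.deviation:.4f})")
print("Small windows resolve the planted level set exactly; beyond the"
      " motif width the averaged peaks drift apart.")
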