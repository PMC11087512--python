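"""Sum PASEF frame-level scans into one composite MS/MS spectrum.

A timsTOF acquires each precursor's fragment signal across several PASEF
frames; the pipeline sums the frame-level scans, merging peaks that agree
within a ppm tolerance. Total intensity is conserved exactly and the merged
m/z is the intensity-weighted mean.
"""

from timsrescore import SyntheticDatasetSpec, generate_dataset, sum_frame_scans

dataset = generate_dataset(SyntheticDatasetSpec(n_peptides=5, seed=11,
                                                n_frames_per_spectrum=10))
composite = dataset.spectra[0]
frames = dataset.frames[composite.spectrum_id]

print(f"spectrum {composite.spectrum_id}: {len(frames)} PASEF frames, "
      f"{len(composite.peaks)} composite peaks")
for k, frame in enumerate(frames[:3]):
    print(f"  frame {k}: {len(frame.peaks):3d} peaks, "
          f"total intensity {frame.total_intensity():.0f}")

summed = sum_frame_scans(frames, merge_tol_ppm=40.0)
print(f"summed:   {len(summed.peaks):3d} peaks, "
      f"total intensity {summed.total_intensity():.0f}")
print(f"composite total intensity {composite.total_intensity():.0f} "
      f"(difference {summed.total_intensity() - composite.total_intensity():.0f})")
print("the zero difference shows summation conserves every detector count")
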