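"""Coarse-grained order fields and the radius scan.

Computes the coarse-grained nematic and hexatic magnitudes of disordered
synthetic tissues over a ladder of coarse-graining radii R (in units of
the mean cell radius R_cell) and reports where the two curves cross.  For
a disordered tissue both curves decay with R because opposing directors
cancel inside larger circles; the crossing radius depends on details of
the descriptors, which is why a "hexatic-nematic crossover length" should
be interpreted with care.
"""

from patic import crossover_detect, radius_scan, voronoi_tissue

frames = [voronoi_tissue(150, box=(12, 12), seed=500 + k, periodic=True, frame=k)
          for k in range(4)]
scan = radius_scan(frames, p_list=(2, 6), R_over_Rcell_list=(1.0, 2.0, 4.0, 8.0))

print(scan.to_dataframe().to_string(index=False))

cross = crossover_detect(scan, 2, 6)
rcell = scan.radii[0] / scan.radii_over_rcell[0]
if isinstance(cross, list) and cross:
    rc = ", ".join(f"{r:.3f} (= {r / rcell:.2f} R_cell)" for r in cross)
    print(f"\nQ2bar and Q6bar curves cross at R = {rc}")
else:
    print(f"\nno Q2bar/Q6bar crossover on this ladder: {cross!r}")
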