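# Example pipeline configuration: a reduced run of every condition
# (n: 20 per cohort for a quick demonstration; the validation runs use 100).
# Cylinder cohorts use the half-scale domain; omit length/domain_edge for
# the full-scale defaults (length 400 in a 500^3 domain).
supersampling: 5
cohorts:
  - {kind: cylinder, n: 20, seed: 100, aspect_ratio: 1.0,  length: 200.0, domain_edge: 250}
  - {kind: cylinder, n: 20, seed: 200, aspect_ratio: 1.25, length: 200.0, domain_edge: 250}
  - {kind: cylinder, n: 20, seed: 300, aspect_ratio: 1.5,  length: 200.0, domain_edge: 250}
  - {kind: cylinder, n: 20, seed: 400, aspect_ratio: 3.0,  length: 200.0, domain_edge: 250}
  - {kind: ellipsoid, n: 20, seed: 500, voxel_size: 0.33, alignment_mode: woven}
  - {kind: ellipsoid, n: 20, seed: 600, voxel_size: 0.33, alignment_mode: parallel_fibred}
  - {kind: ellipsoid, n: 20, seed: 700, voxel_size: 0.8,  alignment_mode: woven}
  - {kind: ellipsoid, n: 20, seed: 800, voxel_size: 0.8,  alignment_mode: parallel_fibred}
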