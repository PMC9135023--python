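# Adult Warmblood horse with anatomically measured forelimb length and
# glenoacetabular distance (used for comparison runs under the limb
# extension work objective).
body:
  mass: 1.0
  g: 9.81
  l_H_max: 1.38        # m
  l_F_max: 1.14        # m, manus to shoulder in standing
  gad: 1.63            # m
  com_fraction: 0.57
  murphy: 0.82
  variant: distributed_mass
task:
  speed: 1.6
  stride_period: 1.16
optimization:
  c1: 0.00003
  n_nodes: 16
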