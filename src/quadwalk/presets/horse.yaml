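# Adult Warmblood horse, simplified geometry: forelimb length and
# glenoacetabular distance set equal to the standing hindlimb length so
# that differences between work objectives, not segment lengths, drive
# the solutions.
body:
  mass: 1.0            # trunk mass (normalizes away; works are per m g l_H)
  g: 9.81              # m s^-2
  l_H_max: 1.38        # m, pes to hip in standing
  l_F_max: 1.38        # m
  gad: 1.38            # m, hips to shoulders
  com_fraction: 0.57   # COM at 0.57 GAD from the hips
  murphy: 0.82         # 4 I / (m GAD^2), dutch warmblood
  variant: distributed_mass
task:
  speed: 1.6           # m s^-1 mean walking speed
  stride_period: 1.16  # s, mean stride time (stride length = speed * period)
optimization:
  c1: 0.00003          # force-rate penalty coefficient
  n_nodes: 16
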