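# quadwalk

Trajectory optimization of planar quadrupedal walking under competing
mechanical-work objectives.

Cursorial quadrupeds walk with a highly stereotyped four-beat pattern:
each leg touches down separately, support alternates between two and three
limbs, duty factors sit near 0.5, and individual-limb ground reaction
forces often show a double hump. `quadwalk` asks which simple measure of
mechanical work *prescribes* that gait when minimized, rather than merely
describing it. It is aimed at locomotion biomechanists and legged-robotics
researchers who want a fully open, scriptable version of this
model-based experiment.

## Model and objectives

The body is a planar rigid trunk (mass `m`, pitch inertia expressed as the
Murphy number `Mu = 4I/(m·GAD²)`) with four massless prismatic legs that
push along the line from a fixed footfall to their hip/shoulder attachment,
subject to `F_i ≥ 0` and the strut complementarity `F_i (l_max,i − l_i) ≥ 0`
(force only while the leg is at or below full extension). Footfall
positions and contact timing emerge from the optimization
(contact-invariant transcription of the symmetric half cycle, direct
collocation, multi-start SQP). A point-mass variant drops the rotational
dynamics but keeps the limb-length geometry.

Three per-stride work objectives are compared (`|·|⁺` is the positive
part; works in units of `m·g·l_H`):

* **Net COM Work**  `NCW = ∫ |F_net · V_com|⁺ dt` — the positive
  fluctuations of COM kinetic + gravitational potential energy;
* **Individual Limbs COM Work**  `ILCW = ∫ Σᵢ |Fᵢ · V_com|⁺ dt`;
* **Limb Extension Work**  `LEW = ∫ Σᵢ |Fᵢ · l̇ᵢ|⁺ dt` — axial actuator
  work of the strut legs.

Net System Work (including rotational energy) and Cavagna percent recovery
are evaluated on every solution. The shipped preset is an adult Warmblood
horse walking at nondimensional speed `U' = 0.43` with stride `D' = 1.34`,
COM at 0.57 GAD from the hips, `Mu = 0.82`.

The central finding this package reproduces: minimizing **NCW** gives a
flat, compliant gait with duty factors near 1 and near-perfect pendular
recovery; minimizing **ILCW** gives alternating single-limb vaulting with
violent pitching; only **LEW with distributed mass** produces the
stereotypical four-beat singlefoot walk.

## Worked example

```python
from quadwalk import horse_preset, build_nlp, multistart, TranscriptionSpec
from quadwalk.gait_metrics import gait_diagram, classify_gait

body, task = horse_preset()          # distributed mass, U'=0.43, D'=1.34
result = multistart(
    lambda: build_nlp(body, task, "lew", TranscriptionSpec(n_nodes=12)),
    n_guesses=10, base_seed=1200,
)
best = result.best                   # pseudoglobal optimum
w = best.works
print(f"lew={w.lew:.4f} ncw={w.ncw:.4f} ilcw={w.ilcw:.4f} "
      f"recovery={w.percent_recovery:.1f}%")
d = gait_diagram(best.trajectory)
print(classify_gait(d, best.trajectory))
print({k: round(v, 2) for k, v in d.duty_factors.items()})
print({k: round(v, 2) for k, v in d.phases.items()})
print(d.support_sequence)
```

Output (a few minutes on one CPU):

```
lew=0.0645 ncw=0.0324 ilcw=0.1369 recovery=59.6%
four_beat_singlefoot
{'LH': 0.58, 'LF': 0.62, 'RH': 0.58, 'RF': 0.62}
{'LH': 0.0, 'LF': 0.23, 'RH': 0.5, 'RF': 0.73}
2-3-2-3-2-3-2-3
```

The extension-work optimum is a four-beat singlefoot: four staggered
touchdowns a quarter-stride apart, support alternating 2-3-2-3, duty
factors near 0.5-0.6, and 0.064 `m·g·l_H` of positive actuator work per
stride. Running the same campaign with `"ncw"` instead yields duty factors
of 0.93-1.0, `NCW ≈ 0.0004` and 99.5% recovery — economical by the COM
measure, nothing like a real walk.

The same runs are available from the shell:

```bash
quadwalk solve --objective lew --variant distributed --preset horse \
    --restarts 10 --seed 1200 --out out/lew
quadwalk validate          # conservative toy-system oracles
```

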