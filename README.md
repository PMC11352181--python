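# gipk — a compact gastrointestinal pharmacokinetic simulator

`gipk` simulates the plasma concentration-time profile of an orally
administered drug with a deliberately small, physiologically interpretable
model, aimed at early drug development when clinical data are scarce: fit
three parameters to one observed curve, then predict other dosages and an
effective intestinal permeability.

## The model

Four gastrointestinal compartments plus the peripheral circulation:

- **Stomach** — the tablet dissolves by Noyes–Whitney kinetics,
  `drp/dt = −4πρ rp² ksd (Ss − Cs)` with `ksd = 3 D Ss / (4πρ)`, where the
  solubility carries a Henderson–Hasselbalch pH correction
  `Ss = S0 (1 + 10^(pH − pKa))`. Gastric juice (`Qgj`) accretes volume
  continuously.
- **Duodenum** — every `Te = 600 s` a discrete event fires: the duodenum
  first discharges its whole content into the jejunum as a *bolus*, then
  receives 1/20 of the current stomach volume at the gastric
  concentration.
- **Jejunum and ileum–colon** — each bolus travels at `u = 1 m/h` down a
  7.5 m conduit while exchanging drug with splanchnic blood flowing
  countercurrent. The axial absorption rate follows a Cauchy profile per
  segment, `α_l(x) = λ_l / (π (1 + (x − L̃_l)²))`, peaked at `Lj/3`
  (jejunum) and `(Lj+Li+Lc)/5` past the jejunum outlet (ileum–colon). The
  blood concentration updates algebraically at each bolus contact,
  `Cb^i = Cb^{i−1} + K_i (C_i − Cb^{i−1})` with
  `K_i = α_i Vbol / (π rbol² (u + vb))`.
- **Peripheral circulation** — a stirred 4 L pool with first-order
  elimination `kd` fed by the chain outlet; its concentration re-enters
  the splanchnic inlet after a delay `δ = 90 s`:
  `Vb dC̄b/dt = Qb (Cb^N − C̄b) − kd C̄b Vb`, `Cb⁰(t) = C̄b(t − δ)`.

Only `λj`, `λic` (absorption scales, tabulated in units of 10⁻³) and `kd`
(1/s) are estimated, by multistart bounded least squares on the
max-normalized curves:

```
φ(λj, λic, kd) = Σ_y [ obs(t_y)/max_y obs − sim(t_y)/max_y sim ]²
```

The fitted profile also yields an effective intestinal permeability,

```
Peff = (rint/Lj) ∫₀^Lj αj dx + (rint/(Li+Lc)) ∫ αic dx    [cm/s]
```

evaluated in closed form via the Cauchy antiderivative.

Physicochemical fixtures for nine drugs (aprepitant, griseofulvin,
linezolid, danazol, fenofibrate, ibuprofen, ketokenazole, ketoprofen,
etoricoxib) and the published fitted parameter triples ship with the
package. Published clinical curves are not redistributable; a synthetic
observation generator (forward model + multiplicative assay noise) stands
in for them, and user-supplied digitized CSVs are accepted everywhere an
observed series is expected.

## Worked example

Generate a noisy synthetic observation series for 80 mg aprepitant, fit
the three parameters, predict the 125 mg curve, and report permeability:

```bash
$ gipk synth --drug Aprepitant --dose-mg 80 --params 5.157,5.100,2.012e-5 \
      --times 1,2,4,6,8,10,12,16,24 --noise-cv 0.05 --seed 3 --out obs.csv
wrote 9 samples to obs.csv

$ gipk fit --obs obs.csv --drug Aprepitant --dose-mg 80 \
      --n-starts 8 --seed 0 --out fit.json
lambda_j = 4.106  lambda_ic = 1.506  kd = 2.176e-05 1/s  phi = 0.008593

$ gipk predict --fit fit.json --drug Aprepitant --dose-mg 125 --out pred125.csv
Cmax = 1.59366 mg/L at Tmax = 10.1 h

$ gipk peff --fit fit.json
Peff = 0.00119144 cm/s (jejunum 0.000990244, ileum-colon 0.000201191)
```

The fit recovers parameters of the right magnitude from nine noisy points
(`phi` is the normalized sum of squares; with `--noise-cv 0` it drops to
~0 and the true triple is recovered to machine precision). The predicted
125 mg curve peaks at the same time as the 80 mg training curve — dose
changes the tablet radius, not the transit schedule — with a proportionally
higher Cmax. `Peff` lands on the 10⁻³ cm/s scale typical of passively
absorbed drugs.

The same operations are available as a library (`gipk.simulate_full`,
`gipk.fit_parameters`, `gipk.predict_dose`, `gipk.effective_permeability`);
see `docs/methods.md` for the modeling details and numerical choices.

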