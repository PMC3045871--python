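# Methods

## Model and assumptions

The simulator is a purely deterministic density model: no individuals are
sampled, no randomness enters anywhere. Three assumptions carry the whole
construction.

1. **One exposure axis.** Every cardiovascular risk factor (including the
   metabolic-syndrome profile) is projected onto systolic blood pressure.
   The population is x ~ N(μ, σ²); the defaults μ = 130, σ = 20 mm Hg
   describe middle-aged Japanese men, for whom BP is the dominant predictor
   of cardiovascular events. People with diabetes or prior cardiovascular
   disease are outside the model's scope, as their risk assessment differs.
2. **Exponential dose–response.** Individual incidence is
   P(x) = (1/l)·exp((x−m)/k). k (default 20, swept over {20, 30, 40} mm Hg)
   sets how fast risk e-folds with SBP; m (140 mm Hg) is where P = 1/l;
   l (100) fixes the absolute scale. Because every post-intervention rate
   is proportional to 1/l, l cancels from all ΔIR ratios — only the shape
   parameters matter.
3. **Convergence crediting.** Post-intervention risk is evaluated with the
   pre-intervention risk function at the post-intervention SBP, and only a
   `contribution` fraction (default 0.5) of any achieved SBP decrease is
   credited, reflecting that risk reduction converges toward the
   lower-pressure level over several years rather than instantly. The
   factor is applied inside the risk argument (a treated 160 mm Hg patient
   with target 140 and adherence 0.7 is evaluated at 160 − 20·0.7·0.5 =
   153 mm Hg), matching the model's individual-level arithmetic, not as a
   multiplier on ΔIR.

## Interventions

**Medication (high-risk).** Three ingredients: the consultation rate
s(x) = 1 − exp(−(x−a)·b), the SBP-lowering effect g(x) = (x−c)·d, and the
initiation threshold e. s(x) is clamped to zero below the alarming SBP a,
where the raw expression would be negative and meaningless; all default
scenarios have e ≥ a + 10, so clamping never affects them. Adherence d
lives inside g(x) while s(x) carries only consultation, which is how the
individual worked example composes (0.45 consultation at 160 mm Hg under
a=140, b=0.03; 7 mm Hg credited lowering under c=140, d=0.7). The four
default policy columns vary (a, b) and (c, d) jointly from ideal
(130, 0.05, 130, 0.8) to pessimistic (160, 0.01, 160, 0.5); a scenario
grid cell is populated only when e ≥ a + 10, and absent cells are reported
as missing, not zero.

**Promotion (population).** A two-component mixture: a fraction β of the
entire population achieves an SBP shift of α mm Hg (credited at
α·contribution), the rest is unchanged. β is either given directly or
aggregated from a stratified campaign table with population shares
10/20/50/20 % (affirmative support, motivating support, information only,
indifferent); the three bundled patterns aggregate to β = 0.1375
(realistic), 0.275 (optimistic), 0.50 (ideal). Since a constant shift of an
exponential risk is a pure rescaling, the post-promotion rate has the exact
closed form C·(1 − β·(1 − e^(−α·contribution/k))), used as the oracle for
the quadrature and making the reduction exactly linear in β.

## Numerics

- **Grid.** Default [10, 250] mm Hg at 1 mm Hg intervals. The integrand
  f·P is itself a Gaussian, centred at μ + σ²/k (150 mm Hg at the
  defaults), so the default bounds capture more than 1 − 10⁻⁶ of its mass;
  a grid that truncates more than that logs a warning rather than failing.
- **Quadrature.** Composite trapezoid on the closed grid by default;
  composite Simpson on a 0.01 mm Hg grid serves as the internal reference
  and agrees within 0.1 % relative on every default scenario.
- **The jump at e.** The medication integrand is discontinuous at the
  initiation threshold. The three-term integral is therefore evaluated as a
  split quadrature — the untreated integrand on [L, e], the treated mixture
  on [e, H] — which removes the O(step·jump) error a masked one-pass sum
  would commit. When e is not a grid node it is inserted into both
  sub-grids. The sampled pre/post curves place the half-sum of the two
  one-sided limits at a node falling exactly on e, so trapezoid integration
  of the sampled gap reproduces ΔIR exactly on aligned grids.
- **Shifted arguments.** x − g(x) and x − α·contribution may fall below the
  grid's lower bound; the risk function is analytic on all reals, so they
  are evaluated directly with no clamping.
- **Precision and display.** All rates are carried in double precision;
  human-readable output rounds to 3 significant digits and N_HC is
  displayed rounded half-up to an integer, with full precision kept in the
  JSON outputs.
- **Degenerate inputs.** σ → 0 concentrates the population at μ (the
  cumulative rate tends to P(μ)); β = 0, α = 0, b → 0 or d = 0 reduce each
  intervention exactly to the baseline. Negative ΔIR (a policy that raises
  risk) is impossible under this model and is treated as an error;
  ΔIR = 0 yields an infinite N_HC, reported as such.

## Design choices

- The comparison declares the larger-ΔIR strategy the winner and reports
  the med/promo ΔIR ratio alongside the promo/med N_HC ratio (identical by
  construction, since N_HC is a reciprocal).
- Configuration is YAML (JSON being a YAML subset), with unknown keys
  rejected by name; an empty config file is the complete default study.
- The CLI is a thin formatting layer; every printed number is re-derivable
  from the library API.

## Known limitations

- The model is point-deterministic: no uncertainty intervals, no
  sensitivity distributions beyond the explicit parameter grids.
- No age/sex structure, no diabetic or secondary-prevention subpopulations,
  no beyond-BP drug effects, and no interaction between concurrent
  medication and promotion — the two strategies are evaluated separately on
  the same baseline.
- The published sensitivity tables this model parallels are not fully
  recoverable from the stated equations: the promotion grid values computed
  here are systematically larger (by a factor varying from ~1.2 at α=20 to
  ~1.45 at α=5, k=20) than their published counterparts, and the two
  least-favourable medication columns differ by ~20–30 %, while the
  favourable medication columns agree to well under 1 %. The implementation
  follows the stated equations and the individual-level worked examples
  exactly and makes no attempt to tune constants toward the published
  cells; the grid's structural properties (linearity in β, ordering in k,
  α and e) hold in both. The headline conclusion — medication prevents more
  events than promotion on the same baseline — is robust to this
  discrepancy (ratio ~1.6 from the equations, ~2.1 from the published
  cells).
- The consultation-rate and adherence functions are assumptive forms
  chosen for analytic convenience; real consultation behaviour is far less
  regular.
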