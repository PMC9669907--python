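# Methods

This note documents the models behind `herdlab`, the defaults and why they
were chosen, and what the synthetic study can and cannot say about real
teams.

## The herding game

The simulated task is a corralling game on a flat 500 × 500 m plane with the
containment area (radius 5 m) at the origin. At trial start the three
ground-player avatars spawn uniformly within 100 m of the center and the
9 or 18 target agents (TAs) uniformly within 180 m. A trial ends in success
the moment every TA has been inside the containment circle for 5 continuous
seconds, otherwise in failure at the 300 s ceiling; failed trials keep the
ceiling duration in all analyses.

### Target-agent dynamics

Each TA is a 1 kg point mass integrated at 90 Hz by semi-implicit Euler:
v ← v + (F/m)Δt, clamped to ‖v‖ ≤ 10 m·s⁻¹, then x ← x + vΔt. Two forces
act:

* **Brownian forcing** — once per second (zero-order hold in between) a
  force with magnitude uniform on [0, 60] N and uniform random direction is
  drawn. With a 1 kg mass and no drag this makes free TAs wander at
  essentially the speed cap, redirecting every second.
* **Repulsion** — every avatar within the 10 m threat radius pushes the TA
  directly away with magnitude F(d) = min(450, 450/d) N. The single-constant
  inverse law is the simplest kernel consistent with an inverse-distance
  force that saturates at 450 N (it hits the cap at d ≤ 1 m); the constant
  is exposed as `SimParams.repulsion_k`. Forces from multiple avatars add;
  only the velocity, not the summed force, is clamped.

The velocity clamp is the sole dissipation: there is no drag term, so a TA
keeps its last velocity until re-forced.

**Containment behavior** (`SimParams.contained_dynamics`). The open-field
dynamics give a TA crossing the 10 m-diameter containment area about one
second before it wanders out again, which would make the all-contained dwell
unreachable for plausible play. The default `"calm"` mode therefore freezes
a contained TA in place — velocity zeroed, Brownian hold suppressed — *as
long as no avatar is within its threat radius*; a threatened contained TA
flees normally and can be knocked back out. This keeps the containment
mechanic meaningful (guards can still scatter the pen) while making success
attainable. `"full"` restores unmodified dynamics everywhere.

Other unstated geometry, decided once and exposed as parameters: the field
boundary reflects (agents cannot leave, and no absorbing corners); a
coincident player/TA pair pushes the TA in a uniformly random direction
drawn from the trial RNG; the late-spawn TA (perturbation trials) appears
uniformly within the 180 m spawn disk at a time drawn uniformly from the
final 90 s, or immediately once all other TAs are contained, whichever
comes first.

### Scripted players

Human play is replaced by a deterministic-given-seed controller, re-planned
at 10 Hz with controls held in between. Each avatar moves at 10 m·s⁻¹
(5 m·s⁻¹ for fine approach; speeds are restricted to the game's {0, 5, 10}
gears). The controller:

* **searches** when no TA is visible — with clear skies (sensing radius
  150 m) each player sweeps an assigned 120° sector boustrophedon-style;
  under fog (sensing radius 10 m) there are no landmarks with which to hold
  a partition, so waypoints are drawn uniformly over the spawn disk and the
  player chases whatever it stumbles into. This single difference is the
  model of why fog makes search slower and more redundant: fog trials run
  longer and the players' search polygons overlap more.
* **drives** a visible TA by moving to a point 5 m radially outward of it
  (inside the threat radius), so the flee response points inward; the goal
  is led by the TA's estimated velocity. A player repositioning to the far
  side routes around the TA's threat circle — a TA sitting between the
  player and the center is flanked, not pushed outward — and transit paths
  detour around the containment area so contained TAs stay calm. Delivered
  TAs are pushed ~2.5 m deep before the player retreats beyond the guard
  ring.

The drone operator has no physical embodiment; fog never changes the
physics, only sensing (and, through the speech generator's condition
targets, how much the operator talks).

## Talk/silence generator

Each of the four speakers is an alternating-renewal process with exponential
on- and off-durations, discretized to 30 Hz frames (the analysis frame rate;
exact 30 Hz frames are used rather than 33.3 ms windows so the coded series
and the RQA operate on one consistent clock). Exponential bouts are the
minimal-assumption renewal model; nothing lexical is generated.

Per-trial talk-proportion targets come from a (role × visibility × targets ×
perturbation) table of means and SDs — the study conditions — jittered per
trial by the tabled SD. Mean utterance durations are 2.0 s (operator, fog),
1.2 s (operator, clear) and 0.8 s (ground players): under fog the operator
issues longer directive utterances, with clear visibility shorter
acknowledgements suffice. Longer bouts raise %DET slightly (fewer isolated
recurrent points per speaking frame), so this choice is what carries the
fog/clear determinism contrast.

A single `coupling` parameter c ∈ [0, 1] (default 0.5) adds conversational
structure: while any other speaker holds the floor a speaker's onset hazard
is multiplied by (1 − c), and for 1 s after each operator offset the ground
players' onset hazard is multiplied by (1 + 1.5·c) — command/response
structure. At c = 0 the speakers are exactly independent renewal processes.
Because the inhibition would otherwise depress realized talk time below
target, base hazards are divided by the expected average multiplier (a
first-order occupancy approximation, exact at c = 0), keeping realized
proportions close to the configured table at the defaults.

## Categorical RQA

Coding levels: operator (1 = speaking), ground (1–3 one ground player,
4 = two or more, operator ignored), team (1 operator alone, 2–4 one ground
player, 5 any overlap). Before plot construction every silence frame gets a
unique label from a strictly decreasing negative counter — non-repetition is
the only property the recoding needs, and a counter is reproducible.

Recurrence is exact code equality (embedding 1, delay 1, no radius). The
line of identity is excluded from numerator and denominator
(%REC = 100·N_rec/(n² − n)); the minimum diagonal line length is 2; %DET of
an empty plot is defined as 0 so condition averages keep every trial. All
conventions are exposed as parameters. Note a finite constant series scores
slightly below 100 %DET: the two single-cell corner diagonals of its plot
are isolated points by construction. Statistics are computed without
materializing the n × n matrix (code multiplicities for counts, per-offset
run-length encoding for lines), which keeps 9,000-frame trials cheap; the
test suite pins exact equality with a brute-force double-loop oracle.

## Search-area overlap

Player trajectories are downsampled to 5 Hz with the first second discarded,
then wrapped in a bounding polygon: the Delaunay triangles of the point set
are thresholded by circumradius (the rolling-circle radius), and the
smallest threshold whose triangle set covers every point and is
edge-connected is located by bisection over the sorted circumradii. If no
threshold improves on keeping the full triangulation the shape *is* the
convex hull and is flagged `convex_hull_fallback`; interior holes are filled
(outer ring only) and flagged. Overlap = area of the union of the three
pairwise intersections (triple overlap counted once) divided by the area of
the union of all three polygons. Geometry predicates and areas use shapely's
exact polygon clipping and shoelace areas; agreement with a 10⁻² m
grid-rasterization oracle is enforced in tests at 1%.

## Statistical models

The 2 × 2 × 2 repeated-measures ANOVA is computed by per-team contrast
algebra: with all factors at two levels every effect is one within-team
contrast L, F(1, n−1) = n·L̄²/s²_L (identical to the squared paired t), the
Greenhouse–Geisser ε is exactly 1 (sphericity needs ≥ 3 levels to bind), and
partial η² = SS_eff/(SS_eff + SS_err). Replicate trials are averaged to one
value per team × cell before the ANOVA — with two trials per cell a
single-value-per-cell analysis needs an aggregate, and the mean is the
obvious one (exposed through the input table). Data are not transformed
before analysis, ceiling effects on duration notwithstanding.

The communication–performance link uses a random-intercept model
y = β₀ + f(X, β_X) + z·β_z + u_team + ε with the full factorial design
(centered ± ½ coding) as covariates, fit by maximum likelihood so the full
and reduced (no-z) fits are comparable; Wald z and a normal 95% CI are
reported for β_z, and Cohen's f² = (R² − R²_red)/(1 − R²) with R² the
squared correlation of fitted (fixed + BLUP intercept) and observed values.
When the ML variance estimate lands exactly on the zero boundary the mixed
fit is replaced by its OLS limit, which is the same model at that boundary.

## The synthetic study, and what it does not show

`run_experiment` simulates 10 teams × 8 cells × 2 blocks (160 trials),
deriving every trial's seed from (master seed, team, cell, block) so results
are reproducible and order-independent; per-session trial order is a seeded
shuffle shared across teams by default (final-session protocol). On the
defaults the study reproduces the qualitative fog signature — longer trials,
higher overlap proportion, more operator talk, higher operator- and
team-level %REC/%DET, lower ground-player %REC under fog — as orderings, and
the acceptance suite asserts exactly those signs.

Limitations to keep in mind:

* The ground players are scripted; their competence, division of labor and
  fog behavior are design choices, not emergent human strategy. Absolute
  durations, containment rates and overlap values characterize the scripts,
  not people.
* The talk series reproduce occupancy and coarse turn-taking structure
  only; real conversation has content, addressees, prosody and much richer
  timing. %DET in particular is close to its ceiling for second-scale
  utterances at 30 Hz, so only its orderings, not its absolute level, are
  meaningful here.
* Empirical effect sizes and F statistics from human play are not
  reproducible from synthetic data and are deliberately out of scope; the
  statistics layer is validated against algebraic oracles instead.
* The ANOVA layer requires complete balanced two-level designs; unbalanced
  or >2-level extensions are out of scope.
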