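# vreeg

Tools for studying **attention in VR-based learning with consumer EEG**,
built around two connected components:

1. a deterministic **supply-chain role-play game engine** — the four-actor
   chain (fruit farmer → manufacturer → distributor → retailer/player →
   customer) with scripted weekly demand, NPC replenishment at a 95%
   service level, lost-sales accounting and player KPIs (revenue, lost
   sales, holding cost, bullwhip ratios); and
2. an **EEG analysis pipeline** for 14-channel consumer-headset recordings
   (AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4; 10-20
   naming) across four time events — eyes-open and eyes-closed baselines,
   a 3-minute virtual lecture and 5 minutes of gameplay: quality screening
   on contact/EEG-quality (CQ/EQ) percent series, artifact epoch
   rejection, five-band FFT absolute power per electrode (θ 4-8, α 8-12,
   βL 12-16, βH 16-25, γ 25-45 Hz), transparent band-ratio
   performance-metric proxies, 0-1 normalized topographic scalp maps, and
   non-parametric group statistics (Shapiro–Wilk, Mann–Whitney U,
   seeded permutation tests, Likert sentiment aggregation).

Because the underlying human recordings are not publicly available, the
package ships a **seeded synthetic cohort generator** with known ground
truth (band-limited oscillations, 1/f noise, movement artifacts, contact
dropouts, and configurable group × event × electrode effects) so every
stage of the analysis can be exercised and validated end to end.

## The models in brief

NPC inventory policy (units/day demand D̄, lead time L days, service
factor z, order cost K, holding cost h):

```
SS  = z · D̄ · L              (safety stock)
ROP = SS + D̄ · L             (reorder point)
EOQ = sqrt(2 · D̄ · K / h)    (order batch; ceil'd to whole units)
```

An NPC orders ⌈EOQ⌉ whenever its inventory position (on hand +
in transit) is at or below ROP. Bullwhip amplification is
var(orders)/var(customer demand) (population variances).

Performance-metric proxies (the vendor's formulas are proprietary; ours
are documented band ratios, per epoch, standardized against the
eyes-open/eyes-closed baseline and squashed to [0, 1] by a logistic):
e.g. *attention* = frontal (βL+βH)/(θ+α), *engagement* = all-channel
β/(α+θ), *relaxation* = occipital α/total; see `docs/methods.md`.

## Worked example

```python
>>> from vreeg import PolicyParams, safety_stock, reorder_point, eoq
>>> p = PolicyParams()          # z=1.645, D̄=7/day, L=1 day, K=h=1
>>> safety_stock(p), reorder_point(p), eoq(p)
(11.515, 18.515, 3.7416573867739413)
```

With a 95% service level and the scripted mean demand of 7 units/day the
NPCs hold ≈11.5 units of safety stock, reorder at ≈18.5 units, and order
in batches of ⌈3.74⌉ = 4.

A full desk-scale experiment (synthetic cohort → quality gate → band
power → scalp maps → statistics → game KPIs):

```bash
$ vreeg demo --seed 0 --out demo_out
kept 7/7 participants; 55 artifacts in demo_out
```

At the study's full scale (9 experimental + 6 control participants, a
+50% high-beta amplitude boost at AF4/F4/F8/FC6 during lecture and
gameplay), the pipeline recovers the injected effect: the largest
normalized high-beta group difference lands on a boosted frontal
electrode, and the pooled attention proxy separates the groups —
experimental mean 0.86 vs control 0.53 over 270 vs 180 pooled 10-s
epochs, Mann–Whitney p ≈ 7e-41 (seed 1). Interpretation: the frontal
beta enhancement raises the frontal β/(θ+α) ratio above each
participant's own baseline, exactly the signature the attention proxy is
built to detect.

## Layout

- `vreeg.scm_game` — game engine, policy maths, KPI report
- `vreeg.synth_eeg` — synthetic cohorts, ground truth, Likert surveys
- `vreeg.eeg_features` — quality gate, epoching, band power, PM proxies
- `vreeg.topo` — normalization, IDW scalp maps, 10-20→MNI lookup
- `vreeg.stats` — normality, Mann–Whitney, permutation, sentiment
- `vreeg.pipeline` / `vreeg.cli` — orchestration, EDF/CSV I/O, `vreeg` CLI

See `docs/methods.md` for model assumptions, parameter defaults and
numerical choices.
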