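# avistability

Trait-hypervolume analysis of how land-use change alters the functional
diversity, redundancy and *stability* of bird assemblages.

Standard functional-diversity (FD) assessments are snapshots: they say how
much trait space an assemblage occupies, not how quickly that space would
collapse if further species were lost. This package implements a full
pipeline for that question, for ecologists working with assemblage survey
data sampled along land-use gradients (PREDICTS-style: sites nested in
blocks nested in study landscapes) plus per-species morphometric and diet
tables (AVONET-style):

1. **Data model** — land-use classification (10 fine / 4 coarse types),
   site aggregation into assemblages, genus-level pseudo-species, trophic
   guild subsets (>60% specialist, >25% broadened).
2. **Trait space** — a two-step PCA strips the dominant body-size factor
   from 7 morphometrics, yielding trophic, locomotory and size axes, plus
   log hand-wing index (dispersal); a balanced Gower dissimilarity combines
   the axes with 9-part diet compositions; principal-coordinates analysis
   embeds each landscape's species in 3-D.
3. **TPDs** — each species is a Gaussian kernel (landscape-common
   normal-reference bandwidth) discretised on a shared 50×50×50 grid
   (125,000 cells); assemblage TPDs are abundance-weighted mixtures.
4. **Metrics** — functional richness `FD = #{c : p_c > 0}`; redundancy
   `R = Σ_c p_c·M_c − 1` (`p_c` assemblage probability, `M_c` species
   covering cell c); relative redundancy `R/(N−1)`; per-species redundancy
   contributions `R − R_without`.
5. **Stability** — sensitivity scores (general response traits, climate
   traits, or rarity); vulnerability
   `V = −ρ_Spearman(sensitivity, species redundancy)`; extinction curves
   (active sensitivity-ordered or passive probability-weighted removal),
   summarised by AUC and half-life t½.
6. **Inference** — signed-sqrt z-scoring, then univariate linear mixed
   models `metric ~ land_use + (1|landscape/block)` (REML; contrasts
   against the least-disturbed level).

A first-class synthetic-data generator produces survey studies with known
filtering truth (trait-conserved species complexes, guild-structured
Dirichlet diets, log-normal abundances, logistic land-use filtering), so
every stage is testable end-to-end without downloads. See
`docs/methods.md` for the models, assumptions and design choices.

## Worked example

The `analysis/` scripts run the whole study on synthetic data:

```bash
python analysis/01_simulate.py --seed 1          # survey data -> results/synth/
python analysis/02_trait_space.py                # axes + embeddings
python analysis/03_functional_metrics.py         # TPDs -> results/metrics.csv
python analysis/04_landuse_models.py             # mixed models -> results/models.csv
python analysis/05_sign_recovery.py              # 25-seed replication
```

With seed 1, step 01 generates 20 landscapes × 4 blocks × 6 land uses from
a 400-species pool; mean assemblage richness falls from 84.0 in pristine
primary vegetation to 48.1 in cropland and 45.2 in intense urban. Step 03
prints the whole-assemblage means:

```
                   n_species  fd_richness  redundancy  resistance_auc_general_traits
pristine_primary      84.012    45596.912      22.920                          0.740
disturbed_primary     75.038    43935.550      21.121                          0.724
young_secondary       62.350    41586.825      18.174                          0.705
plantation            54.862    39754.238      17.436                          0.694
cropland              48.125    38006.662      15.548                          0.685
urban_intense         45.162    36803.638      15.070                          0.686
```

i.e. urban assemblages occupy ~19% fewer grid cells of trait space, hold
~7.9 fewer removable species per occupied cell, and their extinction
curves sag earlier. Step 04 fits the mixed models and prints contrasts on
the z-score scale against the least-disturbed category, e.g.

```
fd_richness:   cropland −1.563*  urban_intense −1.825*
redundancy:    cropland −2.078*  urban_intense −2.221*
resistance AUC (general traits): agriculture −1.116*  urban −1.216*
```

(* = p < 0.05; a contrast of −1 means one standard deviation of the
transformed metric below the primary-vegetation baseline). Step 05 repeats
the full chain over 25 seeds: the negative agriculture and urban contrasts
for FD, redundancy and resistance are recovered in ≥ 96% of runs —
land-use change reduces not only how much functional space is occupied but
how much species loss the remaining function can absorb.

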