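# i2n — sensor-guided image annotation and nutrient analysis

`i2n` is a headless engine for wearable-camera dietary assessment. An
eyeglasses-mounted sensor captures an egocentric image every 10–15 s through
the day, and an upstream classifier labels each image 0 (non-intake) or 1
(food intake). From those labels this package:

1. derives **sensor-detected eating episodes** (SDEEps) and restricts human
   image review to them — in study-scale data that cuts the images needing
   review by roughly an order of magnitude;
2. supports **annotation**: marking SDEEps true/false, creating annotated
   eating episodes (AEEps) with meal labels and image links, and attaching
   food items drawn from several **food-composition databases** registered
   side by side (USDA-SR-, FNDDS-, branded-, and FAO-table-style CSV
   dialects are mapped onto one record model);
3. computes **consumed amount, weight, energy, and nutrients**:
   consumed = initial − leftover (e.g. 1 cup − 1/3 cup = 2/3 cup), converted
   to grams via each food's portion-weight table, then scaled linearly from
   the per-100 g nutrient basis — with exact rational arithmetic, so item,
   episode, and daily totals agree exactly;
4. exports item/episode/day **report tables** (CSV canonical, XLSX mirror)
   including true/false SDEEp tallies, annotation duration (hh:mm:ss), and
   database-usage frequencies.

It is aimed at nutrition researchers processing passive-capture image
streams, and at tool builders who need the bookkeeping (episode boundaries,
portion-to-gram conversion, multi-database harmonization) without a GUI.

## Model summary

* An SDEEp is a maximal run of intake-labeled images; runs separated by at
  most `merge_gap` seconds of non-intake time are merged, and merged
  episodes with fewer than `min_images` intake images are dropped. An
  episode spans first intake timestamp → last intake timestamp + capture
  interval.
* Review burden: `pct_reviewed = 100 · (images inside episodes) / (all
  images)`; `pct_reduction = 100 − pct_reviewed`.
* For a food item with initial amount *a* in portion *p* (gram weight *w_p*)
  and leftover *b* in portion *q*: consumed grams `g = a·w_p − b·w_q`, and
  each nutrient `x` contributes `x_100g · g / 100`. Nutrients missing from a
  source database are flagged as incomplete, never imputed as zero.

## Worked example

```python
import tempfile, os
from i2n import (FoodRegistry, load_database, make_toy_database, simulate_day,
                 study_day_params, episodes_from_labels, review_metrics,
                 mark_sdeep, create_aeep, link_image, add_food_item,
                 summarize_day)
from i2n.annotation import DayAnnotation
from i2n.sensor_events import images_in_episode

d = tempfile.mkdtemp()
registry = FoodRegistry()
path, _ = make_toy_database("sr", 50, seed=1, path=os.path.join(d, "sr.csv"))
registry.register(load_database(path, "sr", "toy-sr"))

project, _truth = simulate_day(study_day_params(seed=1))
episodes = episodes_from_labels(project, merge_gap=60, min_images=1)
m = review_metrics([project], [episodes])
print(f"{m.total_images} images, {m.detected_images} in {len(episodes)} episodes "
      f"-> review {m.pct_reviewed:.2f}% of the day")

day = DayAnnotation(project=project, sdeeps=episodes)
mark_sdeep(episodes[1], True)
lunch = create_aeep(day, "lunch")
link_image(day, lunch, images_in_episode(project, episodes[1])[0])
record = next(r for r in registry.database("toy-sr").records
              if any(p.label == "cup" for p in r.portions))
entry = add_food_item(lunch, record, "semi-solid",
                      initial_amount="1", initial_portion="cup",
                      leftover_amount="1/3", leftover_portion="cup")
q = entry.consumed
print(f"consumed {q.amount} {q.portion} = {float(q.grams):g} g "
      f"= {float(q.energy_kcal):.2f} kcal")
daily = summarize_day(day, registry)
print(f"daily: {daily.n_aeep} AEEp, {daily.n_foods} food(s), "
      f"{float(daily.energy_kcal):.2f} kcal, {float(daily.weight_g):.2f} g")
```

prints

```
3009 images, 204 in 3 episodes -> review 6.78% of the day
consumed 2/3 cup = 160 g = 619.20 kcal
daily: 1 AEEp, 1 food(s), 619.20 kcal, 160.00 g
```

i.e. of the 3,009 images of this simulated day only 204 (6.78 %) fall inside
eating episodes and need review; one cup served with a third of a cup left
over is 2/3 cup consumed, which the 240 g/cup portion table converts to
160 g and the per-100 g energy value scales to 619.20 kcal.

## Command line

```sh
i2n simulate --seed 3 --out sim/              # project + ground truth + toy DBs
i2n episodes --project sim/project.json       # SDEEp boundaries as CSV
i2n metrics  --project sim/project.json       # review-efficiency metrics
i2n db load   --path sim/toy_sr.csv --dialect sr --name toy-sr
i2n db search --query rice --registry sim/registry.yaml
i2n annotate  --project sim/project.json --script script.json \
              --registry sim/registry.yaml --out annotation.json
i2n summarize --annotation annotation.json --registry sim/registry.yaml
i2n report    --annotation annotation.json --registry sim/registry.yaml --out report/
```

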