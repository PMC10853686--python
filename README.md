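# gmunit

A universal interval scale — the **Gross Motor (GM) unit** — for the
difficulty of gross motor development tasks, with the full derivation
pipeline implemented as a Python library and command-line tool.

## The problem

Child gross motor development follows a well-documented progression of
increasingly difficult tasks (lying supine → rolling → sitting →
crawling → standing → walking → hopping), but the many instruments that
measure it were built independently with classical test theory, so their
scores live on incompatible, sample-dependent scales. `gmunit`
implements the theory-driven alternative, modelled on how the Lexile
scale fixed a universal unit for reading: predict task difficulty from
hypothesised causal components, then algebraically anchor the predicted
scale to two universally recognised reference tasks.

## The model

Each gross motor task is rated on three ordinal component measures:
body position (1–12), movement (1–22) and support (1–5). A
*specification equation* maps the ratings to task difficulty:

```
TaskDifficulty = 6.76 + 1.23·BodyPosition + 1.21·Movement + 4.93·Support
```

The coefficients come from forward stepwise OLS of observed GMFM-66 item
difficulties (a Rasch partial-credit-model calibration on an interval
metric) on the component ratings. The scale is then anchored:

* lying supine bringing hands to midline (predicted difficulty 14.13) → **0 GM units**
* walking with hands free (predicted difficulty 61.88) → **100 GM units**

giving `GM = (TaskDifficulty − 14.13) × 2.09`, so one GM unit is 1/100
of the distance between lying supine and unsupported walking. Like
Celsius, the scale extends past its anchors: hopping measures 123 GM
units.

The package ships the 66-item component-rating table and the GM
reference table as bundled fixtures, the regression and anchoring
machinery, and a partial-credit-model simulator/calibrator
(`gmunit.rasch_sim`) that generates the synthetic observed-difficulty
data used to exercise the whole derivation.

## Worked example

```python
>>> from gmunit import ComponentRatings, measure_task, published_equation, default_anchors
>>> anchors = default_anchors()
>>> (anchors.offset, anchors.scale)
(-14.13, 2.09)
>>> measure_task(ComponentRatings(body_position=2, movement=2, support=2))
GMValue(raw=15.403299999999998, rounded=15)
```

A task performed prone (body position 2) with controlled head movement
(movement 2) under full proximal support (support 2) — lifting the head
upright while prone — has predicted difficulty
6.76 + 1.23·2 + 1.21·2 + 4.93·2 = 21.50, which the anchored transform
places at (21.50 − 14.13) × 2.09 = 15.40, reported as **15 GM units**:
about 15 % of the developmental distance from lying supine to
independent walking.

From the shell, the same pipeline over a whole rating table:

```
$ gmunit measure | head -4
item_number,item_name,predicted_difficulty,gm_units
2,SUP: BRINGS HANDS TO MIDLINE,14.13,0
6,SUP: R HAND CROSSES MIDLINE,14.13,0
7,SUP: L HAND CROSSES MIDLINE,14.13,0
```

`gmunit table3` verifies that the published equation plus default
anchors reproduce the bundled 66-row reference table exactly;
`gmunit fit` fits a new specification equation to observed difficulties
and derives anchors from it; `gmunit simulate` generates seeded
synthetic difficulty vectors or partial-credit response matrices.

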