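# Default 53-component atlas (Neuromark fMRI 1.0 template), grouped into seven
# functional domains: subcortical (SCN), auditory (ADN), sensorimotor (SMN),
# visual (VSN), cognitive control (CCN), default mode (DMN), cerebellar (CBN).
# `id` is the 1-based row order used for feature indexing; the number in
# parentheses in each label is the template component number.
#
# Note: row 16, postcentral gyrus (72), is listed under VSN here, keeping the
# template's own grouping, even though a postcentral component would
# anatomically sit with the sensorimotor domain. Edit the `domain:` field below
# if you prefer the anatomical grouping; domain membership is configuration,
# not code.
components:
  - {id: 1,  label: "Caudate (69)",                       domain: SCN, peak_mm: [6.5, 10.5, 5.5]}
  - {id: 2,  label: "Subthalamus/hypothalamus (53)",      domain: SCN, peak_mm: [-2.5, -13.5, -1.5]}
  - {id: 3,  label: "Putamen (98)",                       domain: SCN, peak_mm: [-26.5, 1.5, -0.5]}
  - {id: 4,  label: "Caudate (99)",                       domain: SCN, peak_mm: [21.5, 10.5, -3.5]}
  - {id: 5,  label: "Thalamus (45)",                      domain: SCN, peak_mm: [-12.5, -18.5, 11.5]}
  - {id: 6,  label: "Superior temporal gyrus (21)",       domain: ADN, peak_mm: [62.5, -22.5, 7.5]}
  - {id: 7,  label: "Middle temporal gyrus (56)",         domain: ADN, peak_mm: [-42.5, -6.5, 10.5]}
  - {id: 8,  label: "Postcentral gyrus (3)",              domain: SMN, peak_mm: [56.5, -4.5, 28.5]}
  - {id: 9,  label: "Left postcentral gyrus (9)",         domain: SMN, peak_mm: [-38.5, -22.5, 56.5]}
  - {id: 10, label: "Paracentral lobule (2)",             domain: SMN, peak_mm: [0.5, -22.5, 65.5]}
  - {id: 11, label: "Right postcentral gyrus (11)",       domain: SMN, peak_mm: [38.5, -19.5, 55.5]}
  - {id: 12, label: "Superior parietal lobule (27)",      domain: SMN, peak_mm: [-18.5, -43.5, 65.5]}
  - {id: 13, label: "Paracentral lobule (54)",            domain: SMN, peak_mm: [-18.5, -9.5, 56.5]}
  - {id: 14, label: "Precentral gyrus (66)",              domain: SMN, peak_mm: [-42.5, -7.5, 46.5]}
  - {id: 15, label: "Superior parietal lobule (80)",      domain: SMN, peak_mm: [20.5, -63.5, 58.5]}
  - {id: 16, label: "Postcentral gyrus (72)",             domain: VSN, peak_mm: [-47.5, -27.5, 43.5]}
  - {id: 17, label: "Calcarine gyrus (16)",               domain: VSN, peak_mm: [-12.5, -66.5, 8.5]}
  - {id: 18, label: "Middle occipital gyrus (5)",         domain: VSN, peak_mm: [-23.5, -93.5, -0.5]}
  - {id: 19, label: "Middle temporal gyrus (62)",         domain: VSN, peak_mm: [48.5, -60.5, 10.5]}
  - {id: 20, label: "Cuneus (15)",                        domain: VSN, peak_mm: [15.5, -91.5, 22.5]}
  - {id: 21, label: "Right middle occipital gyrus (12)",  domain: VSN, peak_mm: [38.5, -73.5, 6.5]}
  - {id: 22, label: "Fusiform gyrus (93)",                domain: VSN, peak_mm: [29.5, -42.5, -12.5]}
  - {id: 23, label: "Inferior occipital gyrus (20)",      domain: VSN, peak_mm: [-36.5, -76.5, -4.5]}
  - {id: 24, label: "Lingual gyrus (8)",                  domain: VSN, peak_mm: [-8.5, -81.5, -4.5]}
  - {id: 25, label: "Middle temporal gyrus (77)",         domain: VSN, peak_mm: [-44.5, -57.5, -7.5]}
  - {id: 26, label: "Inferior parietal lobule (68)",      domain: CCN, peak_mm: [45.5, -61.5, 43.5]}
  - {id: 27, label: "Insula (33)",                        domain: CCN, peak_mm: [-30.5, 22.5, -3.5]}
  - {id: 28, label: "Superior medial frontal gyrus (43)", domain: CCN, peak_mm: [-0.5, 50.5, 29.5]}
  - {id: 29, label: "Inferior frontal gyrus (70)",        domain: CCN, peak_mm: [-48.5, 34.5, -0.5]}
  - {id: 30, label: "Right inferior frontal gyrus (61)",  domain: CCN, peak_mm: [53.5, 22.5, 13.5]}
  - {id: 31, label: "Middle frontal gyrus (55)",          domain: CCN, peak_mm: [-41.5, 19.5, 26.5]}
  - {id: 32, label: "Inferior parietal lobule (63)",      domain: CCN, peak_mm: [-53.5, -49.5, 43.5]}
  - {id: 33, label: "Right inferior parietal lobule (79)", domain: CCN, peak_mm: [44.5, -34.5, 46.5]}
  - {id: 34, label: "Supplementary motor area (84)",      domain: CCN, peak_mm: [-6.5, 13.5, 64.5]}
  - {id: 35, label: "Superior frontal gyrus (96)",        domain: CCN, peak_mm: [-24.5, 26.5, 49.5]}
  - {id: 36, label: "Middle frontal gyrus (88)",          domain: CCN, peak_mm: [30.5, 41.5, 28.5]}
  - {id: 37, label: "Hippocampus (48)",                   domain: CCN, peak_mm: [23.5, -9.5, -16.5]}
  - {id: 38, label: "Left inferior parietal lobule (81)", domain: CCN, peak_mm: [45.5, -61.5, 43.5]}
  - {id: 39, label: "Middle cingulate cortex (37)",       domain: CCN, peak_mm: [-15.5, 20.5, 37.5]}
  - {id: 40, label: "Inferior frontal gyrus (67)",        domain: CCN, peak_mm: [39.5, 44.5, -0.5]}
  - {id: 41, label: "Middle frontal gyrus (38)",          domain: CCN, peak_mm: [-26.5, 47.5, 5.5]}
  - {id: 42, label: "Hippocampus (83)",                   domain: CCN, peak_mm: [-24.5, -36.5, 1.5]}
  - {id: 43, label: "Precuneus (32)",                     domain: DMN, peak_mm: [-8.5, -66.5, 35.5]}
  - {id: 44, label: "Precuneus (40)",                     domain: DMN, peak_mm: [-12.5, -54.5, 14.5]}
  - {id: 45, label: "Anterior cingulate cortex (23)",     domain: DMN, peak_mm: [-2.5, 35.5, 2.5]}
  - {id: 46, label: "Posterior cingulate cortex (71)",    domain: DMN, peak_mm: [-5.5, -28.5, 26.5]}
  - {id: 47, label: "Anterior cingulate cortex (17)",     domain: DMN, peak_mm: [-9.5, 46.5, -10.5]}
  - {id: 48, label: "Precuneus (51)",                     domain: DMN, peak_mm: [-0.5, -48.5, 49.5]}
  - {id: 49, label: "Posterior cingulate cortex (94)",    domain: DMN, peak_mm: [-2.5, 54.5, 31.5]}
  - {id: 50, label: "Cerebellum (13)",                    domain: CBN, peak_mm: [-30.5, -54.5, -42.5]}
  - {id: 51, label: "Cerebellum (18)",                    domain: CBN, peak_mm: [-32.5, -79.5, -37.5]}
  - {id: 52, label: "Cerebellum (4)",                     domain: CBN, peak_mm: [20.5, -48.5, -40.5]}
  - {id: 53, label: "Cerebellum (7)",                     domain: CBN, peak_mm: [30.5, -63.5, -40.5]}
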