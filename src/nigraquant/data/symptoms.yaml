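# Default symptom dictionary: a documented, editable stand-in covering the
# key parkinsonian and cognitive symptoms used by the cohort summary.
# Each entry: search_terms (matched case-insensitively at word boundaries)
# and an optional group (a grouping term aggregated as "any member present").
bradykinesia:
  search_terms: [bradykinesia, "slowness of movement", bradykinetic]
rigidity:
  search_terms: [rigidity, "cogwheel rigidity", rigid]
rest_tremor:
  search_terms: ["rest tremor", "resting tremor", "tremor at rest"]
postural_instability:
  search_terms: ["postural instability", "frequent falls", retropulsion]
levodopa_responsiveness:
  search_terms: ["levodopa response", "response to levodopa", "responsive to carbidopa-levodopa"]
gaze_palsy:
  search_terms: ["gaze palsy", "vertical gaze limitation"]
  group: oculomotor_dysfunction
diplopia:
  search_terms: [diplopia, "double vision"]
  group: oculomotor_dysfunction
amnesia:
  search_terms: [amnesia, "memory loss", forgetfulness]
apraxia:
  search_terms: [apraxia]
  group: cortical_signs
aphasia:
  search_terms: [aphasia, "word-finding difficulty"]
  group: cortical_signs
disinhibition:
  search_terms: [disinhibition, "socially inappropriate behavior"]
  group: frontal_signs
perseveration:
  search_terms: [perseveration]
  group: frontal_signs
dream_enactment:
  search_terms: ["dream enactment", "acting out dreams"]
loss_of_smell:
  search_terms: [anosmia, "loss of smell", hyposmia]
visual_hallucinations:
  search_terms: ["visual hallucinations", "seeing things"]
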