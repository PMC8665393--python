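# Canonical 32-item short-form symptom catalog.
#
# severity_items are rated 0 (not present) .. 4 (very much).
# frequency_items are rated 1 (rarely) .. 4 (almost constantly); a 0
# encodes "not present" so every item shares the 0..4 numeric range.
# difficulty_sleeping / difficulty_concentrating ride the severity scale
# but score into the psychological subscale.
severity_items:
  - lack_of_appetite
  - lack_of_energy
  - pain
  - drowsiness
  - constipation
  - dry_mouth
  - nausea
  - vomiting
  - change_in_taste
  - weight_loss
  - feeling_bloated
  - dizziness
  - difficulty_swallowing
  - mouth_sores
  - numbness_or_tingling
  - cough
  - shortness_of_breath
  - diarrhea
  - sweats
  - problems_with_urination
  - itching
  - lack_of_sexual_interest
  - swelling_of_arms_or_legs
  - do_not_look_like_myself
  - hair_loss
  - skin_changes
  - difficulty_sleeping
  - difficulty_concentrating
frequency_items:
  - sadness
  - irritability
  - nervousness
  - anxiety
subscales:
  gdi:
    - sadness
    - irritability
    - nervousness
    - anxiety
    - lack_of_appetite
    - lack_of_energy
    - drowsiness
    - pain
    - constipation
    - dry_mouth
  phys:
    - lack_of_appetite
    - pain
    - constipation
    - lack_of_energy
    - drowsiness
    - nausea
    - vomiting
    - dry_mouth
    - change_in_taste
    - feeling_bloated
    - dizziness
    - weight_loss
  psych:
    - anxiety
    - nervousness
    - sadness
    - difficulty_sleeping
    - difficulty_concentrating
    - irritability
aliases:
  "lack of appetite": lack_of_appetite
  "lack of energy": lack_of_energy
  "feeling drowsy": drowsiness
  "drowsy": drowsiness
  "dry mouth": dry_mouth
  "change in the way food tastes": change_in_taste
  "change in taste": change_in_taste
  "weight loss": weight_loss
  "feeling bloated": feeling_bloated
  "difficulty swallowing": difficulty_swallowing
  "mouth sores": mouth_sores
  "numbness or tingling in hands or feet": numbness_or_tingling
  "numbness/tingling": numbness_or_tingling
  "shortness of breath": shortness_of_breath
  "problems with urination": problems_with_urination
  "lack of sexual interest": lack_of_sexual_interest
  "problems with sexual interest or activity": lack_of_sexual_interest
  "swelling of arms or legs": swelling_of_arms_or_legs
  "i don't look like myself": do_not_look_like_myself
  "hair loss": hair_loss
  "changes in skin": skin_changes
  "skin changes": skin_changes
  "difficulty sleeping": difficulty_sleeping
  "difficulty concentrating": difficulty_concentrating
  "feeling sad": sadness
  "feeling irritable": irritability
  "feeling nervous": nervousness
  "worrying": anxiety
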