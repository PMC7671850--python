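schema: mibot-taxonomy/1
version: 0
categories:
- id: feel_good
  display_name: Feel good
  valence: pro
  reflection_templates:
    pro:
    - I understand, you get pleasure and satisfaction from smoking
    - I get it, smoking simply makes you feel good
  examples:
  - text: I enjoy the feeling that it gives me
    polarity: pro
  observed_count:
    pro: 85
  provenance: seed
  aliases:
  - pleasure
  - feeling good
  - satisfaction
- id: stimulation
  display_name: Stimulation
  valence: pro
  reflection_templates:
    pro:
    - I get it, smoking gives you a stimulating lift
    - I understand, you enjoy the kick a cigarette gives you
  examples:
  - text: The sensation of the tobacco as it catches my throat
    polarity: pro
  observed_count:
    pro: 37
  provenance: seed
  aliases:
  - buzz
  - stimulant
  - nicotine hit
- id: stress
  display_name: Stress
  valence: both
  reflection_templates:
    pro:
    - 'Let me see if I understand: smoking relieves you of stress'
    - I get it, smoking helps you cope with stress
    con:
    - I hear you, running out of cigarettes makes you anxious
    - I understand, smoking brings its own stress for you
  examples:
  - text: Helps me relax and decrease stress
    polarity: pro
  - text: Feeling anxious when I've run out
    polarity: con
  observed_count:
    pro: 177
    con: 2
  provenance: seed
  aliases:
  - stress relief
  - relaxation
  - relaxing
  - calming
- id: routine
  display_name: Routine
  valence: both
  reflection_templates:
    pro:
    - I understand, smoking is a routine you look forward to
    - I get it, smoking is part of the rhythm of your day
    con:
    - I hear you, you smoke out of routine even when you don't want to
    - I understand, the habit has you smoking on autopilot
  examples:
  - text: It something to look forward to doing
    polarity: pro
  - text: routine cigarettes
    polarity: con
  observed_count:
    pro: 9
    con: 5
  provenance: seed
  aliases:
  - habit
- id: addiction
  display_name: Addiction
  valence: both
  reflection_templates:
    pro:
    - I understand, you feel a real craving for nicotine
    - I get it, the addiction itself drives you to smoke
    con:
    - I hear you, being addicted is something you dislike about smoking
    - I understand, you don't like how dependent cigarettes make you
  examples:
  - text: I crave nicotine
    polarity: pro
  - text: The first thing I think of when I wake up is my first cigarette
    polarity: con
  observed_count:
    pro: 55
    con: 1
  provenance: seed
  aliases:
  - craving
- id: in_my_hand
  display_name: In my hand
  valence: pro
  reflection_templates:
    pro:
    - I understand, you like having something in your hand
    - I get it, smoking keeps your hands occupied
  examples:
  - text: Gives me something to occupy my hands with
    polarity: pro
  observed_count:
    pro: 30
  provenance: seed
  aliases:
  - something in my hand
  - handling
  - hands busy
- id: health
  display_name: Health
  valence: both
  reflection_templates:
    pro:
    - I get it, you feel smoking helps your body in some ways
    - I understand, you see some physical benefit in smoking
    con:
    - I hear you, the damage to your health worries you
    - I understand, you are concerned about what smoking does to your health
  examples:
  - text: Cigarettes help with bowel movements
    polarity: pro
  - text: All the health problems smoking is linked to causing
    polarity: con
  observed_count:
    pro: 25
    con: 133
  provenance: seed
  aliases:
  - health problems
  - illness
- id: cost
  display_name: Cost
  valence: con
  reflection_templates:
    con:
    - I hear you, cigarettes cost you a lot of money
    - I understand, the cost of smoking weighs on you
  examples:
  - text: Cost so much for such little joy
    polarity: con
  observed_count:
    con: 67
  provenance: seed
  aliases:
  - money
  - price
  - expense
  - expensive
- id: cool
  display_name: Cool
  valence: pro
  reflection_templates:
    pro:
    - I understand, smoking fits the image you like to project
    - I get it, smoking makes you feel cool
  examples:
  - text: Makes me look cool
    polarity: pro
  observed_count:
    pro: 9
  provenance: seed
  aliases:
  - image
  - looking cool
- id: boredom
  display_name: Boredom
  valence: pro
  reflection_templates:
    pro:
    - I get it, smoking fills the boring moments for you
    - I understand, smoking gives you something to do when you are bored
  examples:
  - text: I smoke out of boredom
    polarity: pro
  observed_count:
    pro: 16
  provenance: seed
  aliases:
  - bored
  - boredom relief
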