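schema: mibot-templates/1
responses:
  purpose:
    - "Hi, I'm a chatbot. My purpose is to have an open, non-judgemental conversation
      with you about smoking and to understand your own reasons for and against it."
    - "Hello! I'm a chatbot built to chat with smokers. I'm here to listen and reflect,
      not to judge — I'd like to understand your reasons for and against smoking."
  permission:
    - "May I have your permission to continue the conversation?"
    - "Is it okay with you if we continue?"
  decline_end:
    - "That's completely fine. Thank you for your time."
  like_smoke:
    - "Do you like to smoke?"
  sentiment_reask:
    - "Sorry, I didn't catch that — do you like to smoke?"
  ask_good:
    - "What is good about smoking?"
  ask_bad:
    - "What is bad about smoking?"
  what_else_pro:
    - "What else do you enjoy about smoking?"
    - "What else do you find positive about smoking?"
    - "Do you have more positive things about smoking? Tell me if you can think of any"
  what_else_con:
    - "What else do you dislike about smoking?"
    - "What is another bad thing about smoking for you?"
    - "Do you have more negative things about smoking? Tell me if you can think of any"
  understood:
    - "I understood '{utterance}' as something related to '{name}'"
    - "You said '{utterance}', which I believe can be classified as '{name}'"
  am_i_right:
    - "Am I right?"
  confirm_reask:
    - "Sorry, I need a yes or no here — was my understanding right?"
  thanks_confirm:
    - "Thank you for confirming my knowledge"
    - "Thanks, that confirmation helps me learn"
  options:
    - "Is it one of the following options? {options}, Other"
  abstain_options:
    - "Hmm, I'm not sure I understood that one. Is it one of the following options?
      {options}, Other"
  options_reask:
    - "Sorry, I didn't recognize that. Is it one of the following options? {options},
      Other"
  ask_new_name:
    - "Can you please tell me what it is in one or two words?"
  thanks_new:
    - "Thank you for teaching me something new!"
  skip_label:
    - "Okay, let's move on."
  cap_reached:
    - "You've given me a lot to work with — thank you. Let's pause the list here."
  summary_single:
    - "You said '{utterance}', which I think is related to {name}"
    - "You said '{utterance}', which I believe is essentially {name}"
  summary_multi:
    - "You said {utterances}, which I think are related to {name}"
  summary_uncategorized:
    - "You also said '{utterance}'"
  summary_check:
    - "Did I summarize everything back correctly?"
  summary_fix:
    - "Sorry about that. For '{utterance}' I understood {name}. The options I know are:
      {options}, Other"
  transition_to_con:
    - "Okay. Let's now chat about the bad things about smoking"
    - "Alright, now let's talk about what you don't like about smoking"
  transition_to_pro:
    - "Okay. Let's now chat about the good things about smoking"
    - "Alright, now let's talk about what you like about smoking"
  exception_intro:
    - "Now I'd like to ask a few questions about the reasons you shared."
  exception_q1:
    - "Please describe a time when you experienced {phrase} and ended up smoking."
  exception_q2:
    - "Please describe a time when you experienced {phrase} and didn't end up smoking"
  exception_q3:
    - "Think back to the time when you were able to prevent yourself from smoking.
      What made it different from when you did smoke?"
  exception_ack:
    - "Thank you for sharing that."
    - "I appreciate you reflecting on that."
    - "Thank you, reflections like that matter."
  generic_reflection:
    - "I see. Thank you for sharing that with me."
    - "I hear you. Thanks for telling me that."
  feedback_q:
    - "Before you finish the study, please take some time to comment on your experience
      chatting with the chatbot. Other than its ability to understand more of your
      responses, what kind of advice can you give us to improve it?"
  ending:
    - "Thank you for chatting with me today. Take care!"
    - "Thanks for the conversation. All the best!"
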