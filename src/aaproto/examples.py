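"""Worked-example protocol fragments in the aa-* vocabulary.

These short documents exercise each element of the vocabulary the way a
study author would write it, and double as the fixtures for the worked
examples in the test suite and the README.  ``RANDOM_BRANCHING`` is a
synthetic reconstruction of the classic randomized-item pattern: a random
generator feeds a conditional that instantiates exactly one of three
multiple-choice groups per run.
"""

TEXTFIELD = '<aa-textfield name="myText" label="allows text entry"></aa-textfield>'

BOXGRID = (
    '<aa-boxgrid name="myGrid" vboxes="5" hboxes="5" width="200" height="200" '
    'top-label="top label" bottom-label="bottom label" '
    'left-label="left label" right-label="right label"></aa-boxgrid>'
)

LIKERT_FIVE = '<aa-likert name="myScale" five></aa-likert>'
LIKERT_SEVEN = '<aa-likert name="myScale" seven></aa-likert>'

VARIABLE = '<aa-variable name="myVariable" value="myValue"></aa-variable>'

GEOLOCATION = '<aa-geolocation name="myLocation"></aa-geolocation>'

FUNCTION_RANDOM = (
    '<aa-function-random name="myVariable" min="0" max="10">'
    "</aa-function-random>"
)

MULTIPLE_CHOICE = """\
<aa-multiple-choice name="choices">
  <aa-choice-item value="1">choice 1</aa-choice-item>
  <aa-choice-item value="2">choice 2</aa-choice-item>
  <aa-choice-item value="3">choice 3</aa-choice-item>
  <aa-choice-item value="4">choice 4</aa-choice-item>
</aa-multiple-choice>
"""

#: a screen mixing plain HTML content with (unnamed, display-only) widgets
SCREEN_WITH_CONTENT = """\
<aa-screen>
  <div>Content can be placed as needed to communicate with users</div>
  <p><aa-textfield label="please type something"></aa-textfield></p>
  <p>please make a selection: <aa-likert></aa-likert></p>
</aa-screen>
"""

CHOOSE = """\
<aa-choose>
  <aa-when test="myVariable=='myValue'">'myValue' is the value of myVariable</aa-when>
  <aa-when test="myVariable=='otherValue'">'otherValue' is the value of myVariable</aa-when>
  <aa-otherwise>myVariable has a different value</aa-otherwise>
</aa-choose>
"""

SEQUENCE_THREE_SCREENS = """\
<aa-sequence>
  <aa-screen>first</aa-screen>
  <aa-screen>second</aa-screen>
  <aa-screen>third</aa-screen>
</aa-sequence>
"""

#: four sampling days (one single day plus an inclusive three-day range)
#: times three daily times = twelve concrete triggers
SESSION_TWELVE_TRIGGERS = (
    '<aa-session dates="01/08/2018;03/08/2018-05/08/2018" '
    'times="10:00;15:00;20:00"></aa-session>'
)

#: synthetic reconstruction of the randomized-branching pattern: the
#: generator stores 1..3 into random_choice, then the conditional
#: instantiates exactly one of three multiple-choice groups per run
RANDOM_BRANCHING = """\
<aa-sequence>
  <aa-function-random name="random_choice" min="1" max="3"></aa-function-random>
  <aa-choose>
    <aa-when test="random_choice==1">
      <aa-screen><aa-multiple-choice name="behavior_a">
        <aa-choice-item value="1">I listened attentively</aa-choice-item>
        <aa-choice-item value="2">I spoke my mind</aa-choice-item>
      </aa-multiple-choice></aa-screen>
    </aa-when>
    <aa-when test="random_choice==2">
      <aa-screen><aa-multiple-choice name="behavior_b">
        <aa-choice-item value="1">I made a compromise</aa-choice-item>
        <aa-choice-item value="2">I avoided the discussion</aa-choice-item>
      </aa-multiple-choice></aa-screen>
    </aa-when>
    <aa-when test="random_choice==3">
      <aa-screen><aa-multiple-choice name="behavior_c">
        <aa-choice-item value="1">I criticized the other</aa-choice-item>
        <aa-choice-item value="2">I expressed affection</aa-choice-item>
      </aa-multiple-choice></aa-screen>
    </aa-when>
  </aa-choose>
</aa-sequence>
"""

#: a complete, lint-clean daily-diary study: three prompts a day over four
#: days, a mood likert, a company question, adaptive text re-using the
#: company answer, and a follow-up shown only when the participant was
#: with other people
DIARY_PROTOCOL = """\
<h1>Daily social diary</h1>
<aa-session dates="01/08/2018;03/08/2018-05/08/2018" times="10:00;15:00;20:00">
  <aa-sequence>
    <aa-screen>
      <p>How do you feel right now?</p>
      <aa-likert name="mood" five label="very bad to very good"></aa-likert>
      <aa-multiple-choice name="company">
        <aa-choice-item value="alone">I am alone</aa-choice-item>
        <aa-choice-item value="others">I am with others</aa-choice-item>
      </aa-multiple-choice>
    </aa-screen>
    <aa-choose>
      <aa-when test="company=='others'">
        <aa-screen>
          <p>You said you are with others ({{company}}).</p>
          <aa-likert name="social_pleasant" seven label="how pleasant is the company"></aa-likert>
        </aa-screen>
      </aa-when>
      <aa-otherwise>
        <aa-screen>
          <aa-textfield name="activity" label="what are you doing"></aa-textfield>
        </aa-screen>
      </aa-otherwise>
    </aa-choose>
  </aa-sequence>
</aa-session>
"""
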