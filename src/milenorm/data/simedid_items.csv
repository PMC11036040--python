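item_id,domain,index,label
MG1,gross_motor,1,Hold their head when carried
MG2,gross_motor,2,Lift their chin off the floor
MG3,gross_motor,3,"From the prone position, they can lift their head to 90 degrees"
MG4,gross_motor,4,Support head when lifted by hands
MG5,gross_motor,5,Flip over
MG6,gross_motor,6,"Raise head, shoulders, and chest from a prone position"
MG7,gross_motor,7,Start creeping
MG8,gross_motor,8,Start crawling position
MG9,gross_motor,9,Stand up with support
MG10,gross_motor,10,Sits up unassisted
MG11,gross_motor,11,Crawl with displacement alternating knees and hands
MG12,gross_motor,12,Take steps with help
MG13,gross_motor,13,Stand up unassisted
MG14,gross_motor,14,Walk without help
MG15,gross_motor,15,They crouch and stand up
MG16,gross_motor,16,Walk well with cross-scroll
MG17,gross_motor,17,"Run, they may fall"
MG18,gross_motor,18,Throw ball
MG19,gross_motor,19,Kick the ball
MG20,gross_motor,20,Run showing coordination in their movements
MG21,gross_motor,21,"Run well, stops and start again without falling"
MG22,gross_motor,22,Jump with feet together
MG23,gross_motor,23,Jump moving with both feet
MG24,gross_motor,24,Stand on one foot for 3 seconds
MG25,gross_motor,25,Stand on tiptoe with both feet
MG26,gross_motor,26,Walk on tiptoe
MG27,gross_motor,27,Walk in a straight line keeping balance
MG28,gross_motor,28,Jump on one foot without support
MG29,gross_motor,29,Can catch a ball with both hands
MG30,gross_motor,30,Bounce and catch the ball
MG31,gross_motor,31,Stand on one foot for 5 seconds
MG32,gross_motor,32,Jump moving with one foot
MG33,gross_motor,33,Jump alternating feet
MF1,fine_motor,1,Palmar grasp reflex
MF2,fine_motor,2,Stare the midline
MF3,fine_motor,3,Visually focuses on an object and tracks it horizontally
MF4,fine_motor,4,Keep hands open when awake
MF5,fine_motor,5,Hold an object in hand
MF6,fine_motor,6,Show interest in putting an object in their mouth
MF7,fine_motor,7,Visually focus on an object and follow it from top to bottom
MF8,fine_motor,8,Grasp large objects voluntarily
MF9,fine_motor,9,Hold an object in each hand
MF10,fine_motor,10,Pass an object from one hand to another
MF11,fine_motor,11,Pick up small objects as if their fingers were a rake
MF12,fine_motor,12,Find the object under a blanket
MF13,fine_motor,13,Put and take out objects from the container
MF14,fine_motor,14,Grasp with thumb and forefinger (tweezers)
MF15,fine_motor,15,Pick up a spoon and brings it to their mouth
MF16,fine_motor,16,Scribble
MF17,fine_motor,17,Push a car
MF18,fine_motor,18,Turn pages of a book
MF19,fine_motor,19,Make a tower of two cubes
MF20,fine_motor,20,Put nails on a board
MF21,fine_motor,21,Make a tower of six cubes
MF22,fine_motor,22,Make a ball of paper
MF23,fine_motor,23,Tear paper with both hands
MF24,fine_motor,24,Make shapes with putty
MF25,fine_motor,25,Rotate hand to unscrew
MF26,fine_motor,26,String
MF27,fine_motor,27,Copy a horizontal and vertical line
MF28,fine_motor,28,Copy a circle
MF29,fine_motor,29,Copy a cross
MF30,fine_motor,30,Know how to button and unbutton
MF31,fine_motor,31,Color without leaving the outline of the drawing
MF32,fine_motor,32,Draw a human figure
MF33,fine_motor,33,Cut paper with scissors
DL1,language,1,Calm down when speaking to them
DL2,language,2,Startle or jump in response to sounds
DL3,language,3,Cry to express needs
DL4,language,4,They laugh
DL5,language,5,Make sounds with the throat
DL6,language,6,Turn their head when they search for a sound
DL7,language,7,React when called by their name
DL8,language,8,"Pronounce syllables like Ma, Pa, Ba, Ta"
DL9,language,9,Point with their finger when they want something
DL10,language,10,"Repeat the same syllable twice “Dada, Mama, Mimi, Tata, Papa, Yaya, Baba”"
DL11,language,11,Understand the meaning of the word no
DL12,language,12,Follow one-step commands
DL13,language,13,Follow two-step instructions
DL14,language,14,Answer with yes or no
DL15,language,15,Pronounce their first words with communicative intention
DL16,language,16,Recognize at least 6 objects
DL17,language,17,Point to 5 parts of their body
DL18,language,18,Use a two-word phrase
DL19,language,19,Say 6 words
DL20,language,20,Say their name
DL21,language,21,Know the use of three or more objects
DL22,language,22,Can identify 10 objects by name
DL23,language,23,Pronounce sentences of three words
DL24,language,24,Use more than 15 words
DL25,language,25,Use long sentences
DL26,language,26,Know the qualities or characteristics of an object
DL27,language,27,Pronounce the sounds of words correctly
DL28,language,28,Describe the drawing
DL29,language,29,Name at least three things in a category
DL30,language,30,Recognize opposites
DL31,language,31,Can count up to 5 or more objects
DL32,language,32,Answer two comprehension questions
DL33,language,33,Compare objects
DL34,language,34,Tell a story from a sequence of images
DS1,socioemotional,1,Calm down with family members or caregivers
DS2,socioemotional,2,Smile spontaneously
DS3,socioemotional,3,Smile in response to a person
DS4,socioemotional,4,Recognize the voice of the main caregiver
DS5,socioemotional,5,Make eye contact
DS6,socioemotional,6,Touch the examiner's hands
DS7,socioemotional,7,They are aware of their hands (body)
DS8,socioemotional,8,Try to hold a cup when being fed
DS9,socioemotional,9,Respond to a conversation
DS10,socioemotional,10,Raise their arms or indicate that they want to be carried
DS11,socioemotional,11,Laugh out loud
DS12,socioemotional,12,Explore their face when they are in front of the mirror
DS13,socioemotional,13,Show interest or intention to feed themselves
DS14,socioemotional,14,Look for continuing the game
DS15,socioemotional,15,Explore the environment
DS16,socioemotional,16,Participate in games
DS17,socioemotional,17,Wave or verbally greet
DS18,socioemotional,18,Express their satisfaction when they achieve something
DS19,socioemotional,19,Take a glass without spilling
DS20,socioemotional,20,Imitate adult actions
DS21,socioemotional,21,Recognize their belongings
DS22,socioemotional,22,Express interest in playing with other children
DS23,socioemotional,23,Symbolic game
DS24,socioemotional,24,Refer to themselves as “I”
DS25,socioemotional,25,Say the names of the people with whom they live
DS26,socioemotional,26,They urinate or defecate independently without dirtying their clothes
DS27,socioemotional,27,Indicate in some way that they need to urinate or defecate
DS28,socioemotional,28,Identify basic emotions in images
DS29,socioemotional,29,Come up with games
DS30,socioemotional,30,Share their belongings
DS31,socioemotional,31,Recognize basic emotions in themselves and express them verbally
DS32,socioemotional,32,Recognize and express basic emotions in others
DS33,socioemotional,33,Participate in games respecting rules and turns
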